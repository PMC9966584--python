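"""Binarization, additive totals and the three-stage funnel."""

import numpy as np
import pytest

from probioscreen.data_model_io import (
    ValidationError,
    fixture_path,
    read_survival_table,
    read_typing_table,
)
from probioscreen.group_stats import GroupedMeasurements
from probioscreen.selection_funnel import (
    DEFAULT_SPECIES_QUOTA,
    IncompleteRecordError,
    SelectionConfig,
    binarize_traits,
    step1_select,
    step2_select,
    step3_select,
)

#: Printed additive totals of the criteria grid.
PRINTED_TOTALS = {
    "C01": 3, "C27": 4, "C47": 2, "C31": 5, "C32": 4, "C33": 3, "C36": 4,
    "C46": 4, "C03": 2, "C10": 4, "C17": 1, "C28": 3, "C40": 2, "C26": 1,
    "C67": 2, "C61": 2,
}

STAGE2_EXPECTED = {"C01", "C27", "C31", "C32", "C46", "C10", "C28"}


def base_panel(**overrides):
    panel = {
        "strain_id": "T1",
        "species": "Candida haemuloni",
        "biomass_g_per_L": 0.5,
        "enzyme_total": 3,
        "hemolysis": "gamma",
        "halo_mm": 0.0,
        "biofilm_od": 0.2,
        "autoaggregation_1h_pct": 5.0,
        "hydrophobicity_xylene_pct": 10.0,
    }
    panel.update(overrides)
    return panel


class TestBinarize:
    def test_worked_example_c31(self, trait_panels):
        rec = binarize_traits(trait_panels["C31"])
        assert rec.total == 5
        assert rec.flags == {
            "biomass": True,
            "enzymes": True,
            "hemolysis_observed": False,
            "antagonism": False,
            "biofilm": True,
            "autoaggregation": True,
            "hydrophobicity": True,
        }

    def test_worked_example_c27(self, trait_panels):
        rec = binarize_traits(trait_panels["C27"])
        assert rec.total == 4
        assert not rec.flags["autoaggregation"]

    def test_every_printed_total_reproduced(self, selection_records):
        assert {r.strain_id: r.total for r in selection_records} == PRINTED_TOTALS

    def test_all_reference_strains_nonhemolytic(self, selection_records):
        assert all(r.safety_pass for r in selection_records)

    def test_all_below_threshold_scores_zero_but_safe(self):
        rec = binarize_traits(base_panel())
        assert rec.total == 0
        assert rec.safety_pass

    def test_missing_value_lists_the_gap(self):
        panel = base_panel()
        del panel["biofilm_od"]
        with pytest.raises(IncompleteRecordError, match="biofilm_od"):
            binarize_traits(panel)

    def test_raising_thresholds_never_raises_totals(self, trait_panels):
        base_cfg = SelectionConfig()
        stricter = SelectionConfig(
            biomass_min_g_per_L=1.5,
            enzyme_min_count=9,
            biofilm_od_min=1.2,
            hydrophobicity_min_pct=50,
            autoaggregation_min_pct=30,
            halo_min_mm=2,
        )
        for panel in trait_panels.values():
            assert (
                binarize_traits(panel, stricter).total
                <= binarize_traits(panel, base_cfg).total
            )


@pytest.fixture()
def typing(fixtures_dir):
    return read_typing_table(fixtures_dir / "typing_biomass.tsv")


class TestStage1:

    def test_one_representative_per_pattern_gives_16(self, typing):
        assert len(step1_select(typing)) == 16

    def test_per_species_pattern_counts(self, typing):
        counts = (
            typing.drop_duplicates("rapd_pattern")
            .groupby("species")["rapd_pattern"]
            .count()
            .to_dict()
        )
        assert counts == {
            "Candida haemuloni": 3,
            "Candida parapsilosis": 5,
            "Debaryomyces hansenii": 5,
            "Debaryomyces sp.": 2,
            "Naganishia sp.": 1,
        }

    def test_highest_biomass_representative(self, typing):
        selected = step1_select(typing)
        # pattern C has a single member; pattern B's top producer is C44
        assert "C27" in selected
        assert "C44" in selected and "C01" not in selected

    def test_override_replaces_representative(self, typing):
        selected = step1_select(typing, representative_override={"B": "C01"})
        assert "C01" in selected and "C44" not in selected

    def test_tie_breaks_to_smallest_id(self):
        import pandas as pd

        typing = pd.DataFrame(
            {
                "isolate_id": ["C09", "C02"],
                "species": ["s", "s"],
                "biomass_g_per_L": [1.0, 1.0],
                "rapd_pattern": ["A", "A"],
            }
        )
        assert step1_select(typing) == ["C02"]

    def test_single_pattern_dataset(self):
        import pandas as pd

        typing = pd.DataFrame(
            {
                "isolate_id": ["X1"],
                "species": ["s"],
                "biomass_g_per_L": [0.5],
                "rapd_pattern": ["A"],
            }
        )
        assert step1_select(typing) == ["X1"]

    def test_pattern_without_biomass_is_an_error(self):
        import pandas as pd

        typing = pd.DataFrame(
            {
                "isolate_id": ["X1"],
                "species": ["s"],
                "biomass_g_per_L": [np.nan],
                "rapd_pattern": ["Q"],
            }
        )
        with pytest.raises(ValidationError, match="Q"):
            step1_select(typing)


class TestStage2:
    def test_default_quota_selects_the_seven(self, selection_records):
        ids, rules = step2_select(selection_records)
        assert set(ids) == STAGE2_EXPECTED
        assert len(ids) == 7

    def test_tie_on_total_resolved_by_enzyme_count(self, selection_records):
        ids, rules = step2_select(selection_records)
        # C32, C36, C46 all score 4; C36 has the lowest enzyme count (8 vs 9)
        assert "C36" not in ids
        assert {"C32", "C46"} <= set(ids)
        assert "lowest" in rules["C36"] or "beyond quota" in rules["C36"]

    def test_rare_species_floor_drops_weak_species(self, selection_records):
        ids, rules = step2_select(selection_records)
        assert "C61" not in ids
        assert "below" in rules["C61"] and "floor" in rules["C61"]

    def test_hemolytic_strain_gated_out(self):
        records = [
            binarize_traits(
                base_panel(strain_id="BAD", hemolysis="beta", biomass_g_per_L=2.0)
            ),
            binarize_traits(base_panel(strain_id="OK", biomass_g_per_L=2.0)),
        ]
        ids, rules = step2_select(
            records, SelectionConfig(species_quota={"Candida haemuloni": 2})
        )
        assert ids == ["OK"]
        assert "safety" in rules["BAD"]

    def test_single_strain_species_without_quota_map(self):
        rec = binarize_traits(base_panel(biomass_g_per_L=2.0, enzyme_total=9))
        ids, _ = step2_select([rec], SelectionConfig())
        assert ids == ["T1"]

    def test_empty_records_rejected(self):
        with pytest.raises(ValidationError):
            step2_select([])


class TestStage3:
    @staticmethod
    def _endpoint_groups(path, endpoint):
        df = read_survival_table(path)
        labels, values = [], []
        for g, sub in df.groupby("group", sort=False):
            end = sub[sub["hour"] == endpoint]
            labels.append(str(g))
            values.append(
                (100.0 * end["alive"] / end["n0"]).to_numpy(dtype=float)
            )
        return GroupedMeasurements(labels, values)

    def test_reference_outcome_reproduced(self, fixtures_dir):
        safety = self._endpoint_groups(
            fixtures_dir / "survival_safety_synthetic.tsv", 24
        )
        stress = self._endpoint_groups(
            fixtures_dir / "survival_stress_synthetic.tsv", 8
        )
        final, report = step3_select(
            sorted(STAGE2_EXPECTED), safety, stress, seed=0
        )
        assert set(final) == {"C27", "C10", "C28"}
        assert report["safety"]["significantly_below_control"] == ["C32"]
        assert report["stress"]["significantly_below_control"] == ["C01", "C31", "C46"]

    def test_no_difference_retains_all(self):
        rng = np.random.default_rng(6)
        labels = ["control", "A", "B"]
        values = [rng.normal(50, 3, 3) for _ in labels]
        data = GroupedMeasurements(labels, values)
        final, _ = step3_select(["A", "B"], data, data, seed=0)
        assert final == ["A", "B"]

    def test_missing_control_rejected(self):
        data = GroupedMeasurements(["A", "B"], [np.ones(3), np.zeros(3)])
        with pytest.raises(ValidationError):
            step3_select(["A"], data, data)

    def test_funnel_stages_are_nested(self, fixtures_dir, selection_records):
        typing = read_typing_table(fixtures_dir / "typing_biomass.tsv")
        stage1 = set(step1_select(typing, {"B": "C01", "L": "C17"}))
        stage2, _ = step2_select(selection_records)
        safety = self._endpoint_groups(
            fixtures_dir / "survival_safety_synthetic.tsv", 24
        )
        stress = self._endpoint_groups(
            fixtures_dir / "survival_stress_synthetic.tsv", 8
        )
        stage3, _ = step3_select(stage2, safety, stress, seed=0)
        assert set(stage2) <= stage1
        assert set(stage3) <= set(stage2)
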