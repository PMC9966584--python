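"""Threshold binarization and the three-stage candidate selection funnel.

The screen reduces 39 isolates to 16 dereplicated strains (one
representative per RAPD pattern, by biomass), then to 7 strains by additive
multi-criteria scoring under per-species quotas, then to a final safety- and
stress-vetted set by many-to-one survival comparisons against an
uninoculated control group.

Scoring criteria and thresholds (a strain scores one point per satisfied
criterion):

======================  =========================================
biomass                 >= 1.0 g/L dry weight (at reported precision)
enzymes                 >= 8 active API-ZYM enzymes
antagonism              inhibition halo > 1 mm
biofilm                 crystal-violet OD600 > 0.8
autoaggregation         > 20% at 1 h
hydrophobicity          > 20% against xylene
hemolysis               recorded; alpha/beta fails the safety gate
======================  =========================================

Hemolysis is a hard safety gate, not a beneficial point: a gamma
(nonhemolytic) strain passes with no score contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .data_model_io import ValidationError
from .group_stats import GroupedMeasurements, dunnett_vs_control
from .trait_metrics import antagonism_positive, autoaggregation_positive, hemolysis_classify

__all__ = [
    "SelectionConfig",
    "SelectionRecord",
    "IncompleteRecordError",
    "binarize_traits",
    "step1_select",
    "step2_select",
    "step3_select",
]


class IncompleteRecordError(ValueError):
    """A trait panel is missing values required for binarization."""


#: Default per-species stage-2 quotas of the screen.
DEFAULT_SPECIES_QUOTA = {
    "Candida haemuloni": 2,
    "Candida parapsilosis": 3,
    "Debaryomyces hansenii": 2,
}


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds and quotas of the selection funnel (defaults = the screen's).

    ``species_quota=None`` disables quotas: every strain tied with its
    species' best total is kept instead.
    """

    biomass_min_g_per_L: float = 1.0
    enzyme_min_count: int = 8
    biofilm_od_min: float = 0.8
    hydrophobicity_min_pct: float = 20.0
    autoaggregation_min_pct: float = 20.0
    autoaggregation_time_h: float = 1.0
    halo_min_mm: float = 1.0
    species_quota: Optional[Mapping[str, int]] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_QUOTA)
    )
    rare_species_biomass_floor: float = 0.7

    def __post_init__(self) -> None:
        for name in (
            "biomass_min_g_per_L",
            "enzyme_min_count",
            "biofilm_od_min",
            "hydrophobicity_min_pct",
            "autoaggregation_min_pct",
            "halo_min_mm",
            "rare_species_biomass_floor",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


CRITERIA = (
    "biomass",
    "enzymes",
    "hemolysis_observed",
    "antagonism",
    "biofilm",
    "autoaggregation",
    "hydrophobicity",
)


@dataclass
class SelectionRecord:
    strain_id: str
    species: str
    flags: dict  # the 7 criteria -> bool
    total: int
    safety_pass: bool
    biomass_g_per_L: float
    enzyme_count: int
    selected: dict = field(default_factory=dict)  # stage name -> bool


_REQUIRED_TRAITS = (
    "biomass_g_per_L",
    "enzyme_total",
    "hemolysis",
    "halo_mm",
    "biofilm_od",
    "autoaggregation_1h_pct",
    "hydrophobicity_xylene_pct",
)


def binarize_traits(panel: Mapping, cfg: SelectionConfig = SelectionConfig()) -> SelectionRecord:
    """Score one strain's trait panel against the selection thresholds.

    ``panel`` is a mapping with keys ``strain_id``, ``species`` and the seven
    criterion inputs. The total counts positive flags as displayed in the
    criteria grid; the hemolysis flag records *observed* lysis and, being
    gamma for a safe strain, contributes nothing — it sets ``safety_pass``
    instead. The biomass and enzyme thresholds are inclusive at the reported
    precision; all other thresholds are strict.
    """
    missing = [
        k for k in _REQUIRED_TRAITS if k not in panel or pd.isna(panel[k])
    ]
    if missing:
        raise IncompleteRecordError(
            f"strain {panel.get('strain_id', '?')}: missing trait value(s) {missing}"
        )
    hemolytic = hemolysis_classify(panel["hemolysis"])
    flags = {
        "biomass": float(panel["biomass_g_per_L"]) >= cfg.biomass_min_g_per_L,
        "enzymes": int(panel["enzyme_total"]) >= cfg.enzyme_min_count,
        "hemolysis_observed": hemolytic,
        "antagonism": antagonism_positive(float(panel["halo_mm"])),
        "biofilm": float(panel["biofilm_od"]) > cfg.biofilm_od_min,
        "autoaggregation": float(panel["autoaggregation_1h_pct"])
        > cfg.autoaggregation_min_pct,
        "hydrophobicity": float(panel["hydrophobicity_xylene_pct"])
        > cfg.hydrophobicity_min_pct,
    }
    return SelectionRecord(
        strain_id=str(panel["strain_id"]),
        species=str(panel.get("species", "")),
        flags=flags,
        total=sum(flags.values()),
        safety_pass=not hemolytic,
        biomass_g_per_L=float(panel["biomass_g_per_L"]),
        enzyme_count=int(panel["enzyme_total"]),
    )


def step1_select(
    typing: pd.DataFrame, representative_override: Optional[Mapping[str, str]] = None
) -> list[str]:
    """Pick one representative isolate per RAPD pattern.

    The default representative is the isolate with the highest mean biomass
    in the pattern (ties go to the lexicographically smallest id);
    ``representative_override`` maps pattern label -> isolate id for patterns
    where a different member should stand for the strain. Patterns unique to
    a species are ordinary patterns and are always represented.
    """
    override = dict(representative_override or {})
    selected: list[str] = []
    for pattern, sub in typing.groupby("rapd_pattern", sort=False):
        if pattern in override:
            forced = override[pattern]
            if forced not in set(sub["isolate_id"]):
                raise ValidationError(
                    f"override {forced!r} is not a member of pattern {pattern}"
                )
            selected.append(forced)
            continue
        biomass = sub["biomass_g_per_L"]
        if biomass.isna().all():
            raise ValidationError(f"pattern {pattern}: no biomass data")
        best = sub.sort_values(
            ["biomass_g_per_L", "isolate_id"], ascending=[False, True]
        ).iloc[0]
        selected.append(str(best["isolate_id"]))
    return selected


def step2_select(
    records: Sequence[SelectionRecord], cfg: SelectionConfig = SelectionConfig()
) -> tuple[list[str], dict]:
    """Per-species ranking by additive total with quotas and exclusions.

    Rules, in order: (i) hemolytic strains fail the safety gate; (ii) a
    species whose best member's biomass is below the rare-species floor is
    dropped entirely; (iii) within each species, strains are ranked by total,
    ties broken by enzyme count then biomass then id, and the per-species
    quota is taken (a species absent from a configured quota map gets quota
    zero; with no quota map at all, every strain tied with the species'
    best total is kept). Returns the selected ids and a per-strain rule log.
    """
    if not records:
        raise ValidationError("no selection records")
    rules: dict = {}
    by_species: dict = {}
    for rec in records:
        if not rec.safety_pass:
            rules[rec.strain_id] = "excluded: hemolytic (safety gate)"
            continue
        by_species.setdefault(rec.species, []).append(rec)

    quota = cfg.species_quota
    selected: list[str] = []
    for species, members in by_species.items():
        best_biomass = max(m.biomass_g_per_L for m in members)
        if best_biomass < cfg.rare_species_biomass_floor:
            for m in members:
                rules[m.strain_id] = (
                    f"excluded: species best biomass {best_biomass:.2f} g/L below "
                    f"floor {cfg.rare_species_biomass_floor}"
                )
            continue
        ranked = sorted(
            members,
            key=lambda m: (-m.total, -m.enzyme_count, -m.biomass_g_per_L, m.strain_id),
        )
        if quota is not None:
            take = int(quota.get(species, 0))
        else:
            best_total = ranked[0].total
            take = sum(1 for m in ranked if m.total == best_total)
        for pos, m in enumerate(ranked):
            if pos < take:
                selected.append(m.strain_id)
                rules[m.strain_id] = (
                    f"selected: rank {pos + 1}/{take} in {species} "
                    f"(total {m.total}, {m.enzyme_count} enzymes)"
                )
            else:
                rules[m.strain_id] = (
                    f"excluded: rank {pos + 1} in {species} beyond quota {take} "
                    f"(total {m.total}, {m.enzyme_count} enzymes)"
                )
    return selected, rules


def step3_select(
    stage2_ids: Sequence[str],
    survival: GroupedMeasurements,
    stress: GroupedMeasurements,
    polyamine_comparison=None,
    control_label: str = "control",
    seed: int = 0,
) -> tuple[list[str], dict]:
    """Final safety/stress vetting by Dunnett comparison to the control.

    A strain is excluded when its larval survival after 24 h immersion, or
    its hyposaline-stress survival, is significantly *below* the control
    group (non-inferiority reading: matching or exceeding the control
    passes). Polyamine comparisons, when given, are reported as supporting
    evidence only — they never exclude a strain.
    """
    report: dict = {"safety": {}, "stress": {}}
    final = list(stage2_ids)
    for name, data in (("safety", survival), ("stress", stress)):
        res = dunnett_vs_control(data, control_label=control_label, seed=seed)
        below = set(res.significantly_below())
        report[name] = {
            "comparisons": res.comparisons,
            "significantly_below_control": sorted(below),
        }
        final = [s for s in final if s not in below]
    if polyamine_comparison is not None:
        report["polyamines"] = polyamine_comparison
    report["final_selected"] = final
    return final, report
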