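"""End-to-end orchestration: typing -> traits -> selection -> statistics -> report.

A single declarative YAML config drives a run. Inputs come either from the
packaged reference fixtures (``mode: fixtures``) or from a directory laid
out like a :class:`~probioscreen.synthetic_data.SimulatedBundle`
(``mode: directory``). The three funnel stages are executed in order and
every decision (representative choice, criterion flags, quota ranks,
control comparisons) lands in the report bundle, which serializes to a
deterministic file set with a checksummed run manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model_io import (
    ReportBundle,
    ValidationError,
    fixture_path,
    read_enzyme_table,
    read_survival_table,
    read_trait_table,
    read_typing_table,
    write_report,
)
from importlib import resources
from .group_stats import GroupedMeasurements
from .rapd_typing import (
    RAPDLane,
    assign_strains,
    bin_fragments,
    jaccard_distance_matrix,
    upgma,
    write_newick,
)
from .selection_funnel import (
    DEFAULT_SPECIES_QUOTA,
    SelectionConfig,
    binarize_traits,
    step1_select,
    step2_select,
    step3_select,
)
from .trait_metrics import enzyme_total, survival_percent

__all__ = [
    "load_config",
    "validate_config",
    "run_pipeline",
    "default_pipeline_config",
    "reference_trait_panels",
]


def reference_trait_panels() -> list[dict]:
    """Per-strain trait panels for the 16 reference strains, assembled from
    the packaged fixtures (biomass and species from the typing table, enzyme
    totals from the panel grid, adhesion and safety traits from the
    adhesion stand-in table). Ready for ``binarize_traits``."""
    inputs = _load_fixture_inputs()
    typing = inputs["typing"]
    traits = inputs["traits"].set_index("strain_id")
    panels = inputs["panels"]
    out = []
    for strain in traits.index:
        row = typing.loc[typing["isolate_id"] == strain].iloc[0]
        trow = traits.loc[strain]
        out.append(
            {
                "strain_id": strain,
                "species": str(row["species"]),
                "biomass_g_per_L": float(row["biomass_g_per_L"]),
                "enzyme_total": enzyme_total(panels[strain]),
                "hemolysis": trow["hemolysis"],
                "halo_mm": float(trow["halo_mm"]),
                "biofilm_od": float(trow["biofilm_od"]),
                "autoaggregation_1h_pct": float(trow["autoaggregation_1h_pct"]),
                "hydrophobicity_xylene_pct": float(trow["hydrophobicity_xylene_pct"]),
            }
        )
    return out


def default_pipeline_config() -> dict:
    """The packaged default run configuration (reference-fixture mode)."""
    with resources.as_file(fixture_path("default_config.yaml")) as p:
        return yaml.safe_load(p.read_text())


def load_config(path) -> dict:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    cfg = yaml.safe_load(p.read_text())
    if not isinstance(cfg, dict):
        raise ValidationError(f"{p}: config must be a mapping")
    return cfg


def validate_config(cfg: dict) -> list[str]:
    """Return a list of problems; strings starting with "warning:" are
    non-fatal. An empty list means the config is valid."""
    problems: list[str] = []
    if "seed" not in cfg:
        problems.append("missing required key: seed")
    mode = cfg.get("inputs", {}).get("mode", "fixtures")
    if mode not in ("fixtures", "directory"):
        problems.append(f"inputs.mode must be fixtures|directory, got {mode!r}")
    if mode == "directory":
        d = cfg.get("inputs", {}).get("dir")
        if not d:
            problems.append("inputs.dir required for directory mode")
        elif not Path(d).exists():
            problems.append(f"inputs.dir does not exist: {d}")
    sel = cfg.get("selection", {})
    for key in (
        "biomass_min_g_per_L",
        "enzyme_min_count",
        "biofilm_od_min",
        "hydrophobicity_min_pct",
        "autoaggregation_min_pct",
        "halo_min_mm",
        "rare_species_biomass_floor",
    ):
        if key in sel and (not isinstance(sel[key], (int, float)) or sel[key] <= 0):
            problems.append(f"selection.{key} must be a positive number")
    known_species = {
        "Candida haemuloni",
        "Candida parapsilosis",
        "Debaryomyces hansenii",
        "Debaryomyces sp.",
        "Naganishia sp.",
    }
    for sp in (sel.get("species_quota") or {}):
        if sp not in known_species and mode == "fixtures":
            problems.append(f"warning: quota names unknown species {sp!r}")
    rapd = cfg.get("rapd", {})
    tol = rapd.get("tolerance", 0.05)
    if not (0 < tol <= 0.2):
        problems.append("rapd.tolerance must be in (0, 0.2]")
    cutoff = rapd.get("cutoff", 85)
    if not (0 < cutoff < 100):
        problems.append("rapd.cutoff must be in (0, 100)")
    return problems


def _selection_config(cfg: dict) -> SelectionConfig:
    sel = dict(cfg.get("selection", {}))
    quota = sel.pop("species_quota", DEFAULT_SPECIES_QUOTA)
    return SelectionConfig(species_quota=quota, **sel)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# input loading


def _load_fixture_inputs() -> dict:
    with resources.as_file(fixture_path("typing_biomass.tsv")) as p:
        typing = read_typing_table(p)
    with resources.as_file(fixture_path("adhesion_traits_synthetic.tsv")) as p:
        traits = read_trait_table(p)
    with resources.as_file(fixture_path("enzyme_panels.tsv")) as p:
        panels = read_enzyme_table(p)
    with resources.as_file(fixture_path("survival_safety_synthetic.tsv")) as p:
        safety = read_survival_table(p)
    with resources.as_file(fixture_path("survival_stress_synthetic.tsv")) as p:
        stress = read_survival_table(p)
    return {
        "typing": typing,
        "traits": traits,
        "panels": panels,
        "safety": safety,
        "stress": stress,
        "lanes": None,
        "assays": None,
    }


def _load_directory_inputs(d: Path) -> dict:
    def need(name: str) -> Path:
        p = d / name
        if not p.exists():
            raise FileNotFoundError(p)
        return p

    typing = read_typing_table(need("typing.tsv"))
    with open(need("lanes.tsv")) as fh:
        lanes_df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    lanes = [
        RAPDLane(
            row.isolate_id,
            tuple(float(s) for s in row.fragment_sizes.split(",") if s),
        )
        for row in lanes_df.itertuples(index=False)
    ]
    panels = read_enzyme_table(need("enzymes.tsv"))
    assays = pd.read_csv(need("assays.tsv"), sep="\t", dtype=str, keep_default_na=False)
    safety = read_survival_table(need("survival_safety.tsv"))
    stress = read_survival_table(need("survival_stress.tsv"))
    return {
        "typing": typing,
        "traits": None,
        "panels": panels,
        "safety": safety,
        "stress": stress,
        "lanes": lanes,
        "assays": assays,
    }


# ---------------------------------------------------------------------------
# stages


def _type_isolates(typing: pd.DataFrame, lanes, rapd_cfg: dict) -> tuple[pd.DataFrame, str]:
    """Ensure every isolate carries a RAPD pattern label.

    When lanes are given, isolates are clustered per species (fingerprints
    are only comparable within a species, as in the source screen) and
    pattern labels are made globally unique in first-appearance order.
    Returns the typing table and the Newick serializations of the trees.
    """
    if lanes is None:
        if "rapd_pattern" not in typing.columns or typing["rapd_pattern"].eq("").any():
            raise ValidationError("no lanes given and typing lacks pattern labels")
        return typing, ""

    by_id = {l.isolate_id: l for l in lanes}
    tolerance = rapd_cfg.get("tolerance", 0.05)
    cutoff = rapd_cfg.get("cutoff", 85)
    patterns: dict = {}
    newicks: list[str] = []
    counter = [0]

    def next_label() -> str:
        import string

        n = counter[0]
        counter[0] += 1
        if n < 26:
            return string.ascii_uppercase[n]
        return string.ascii_uppercase[n // 26 - 1] + string.ascii_uppercase[n % 26]

    for species, sub in typing.groupby("species", sort=False):
        ids = list(sub["isolate_id"])
        missing = [i for i in ids if i not in by_id]
        if missing:
            raise ValidationError(f"no RAPD lane for isolate(s) {missing}")
        if len(ids) == 1:
            patterns[ids[0]] = next_label()
            continue
        matrix = bin_fragments([by_id[i] for i in ids], rel_tolerance=tolerance)
        tree = upgma(jaccard_distance_matrix(matrix), labels=ids)
        newicks.append(write_newick(tree))
        local = assign_strains(tree, similarity_cutoff=cutoff)
        relabel: dict = {}
        for iso in ids:  # first-appearance order within the species
            lab = local[iso]
            if lab not in relabel:
                relabel[lab] = next_label()
            patterns[iso] = relabel[lab]

    out = typing.copy()
    out["rapd_pattern"] = [patterns[i] for i in out["isolate_id"]]
    return out, "\n".join(newicks)


def _derive_trait_table(assays: pd.DataFrame, clusters: dict) -> pd.DataFrame:
    """Aggregate replicate-level assay rows into a per-strain trait panel.

    ``clusters`` maps pattern label -> member isolate ids; the assay table is
    keyed by whichever member was assayed.
    """
    value_assays = {
        "biofilm": "biofilm_od",
        "autoaggregation_1h": "autoaggregation_1h_pct",
        "autoaggregation_24h": "autoaggregation_24h_pct",
        "hydrophobicity_xylene": "hydrophobicity_xylene_pct",
        "hydrophobicity_ethyl_acetate": "hydrophobicity_ethyl_acetate_pct",
        "hydrophobicity_chloroform": "hydrophobicity_chloroform_pct",
    }
    keyed = set(assays["strain_id"])
    rows = []
    for pattern, members in clusters.items():
        assayed = [m for m in members if m in keyed]
        if not assayed:
            continue
        sub = assays[assays["strain_id"] == assayed[0]]
        row: dict = {"assay_key": assayed[0]}
        for assay, col in value_assays.items():
            vals = pd.to_numeric(sub.loc[sub["assay"] == assay, "value"])
            if len(vals):
                row[col] = float(vals.mean())
        hem = sub.loc[sub["assay"] == "hemolysis", "value"]
        row["hemolysis"] = hem.iloc[0] if len(hem) else None
        halo = pd.to_numeric(sub.loc[sub["assay"] == "halo_mm", "value"])
        row["halo_mm"] = float(halo.max()) if len(halo) else None
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    config: dict, out_dir: Optional[str] = None
) -> tuple[ReportBundle, dict]:
    """Execute the full three-stage screen described by ``config``.

    Returns the report bundle and, when ``out_dir`` is given, writes the
    deterministic report file set there; the run manifest (returned either
    way) lists stage counts, final selections, config hash and seed.
    """
    problems = [p for p in validate_config(config) if not p.startswith("warning:")]
    if problems:
        raise ValidationError("invalid config: " + "; ".join(problems))

    seed = int(config["seed"])
    mode = config.get("inputs", {}).get("mode", "fixtures")
    if mode == "fixtures":
        inputs = _load_fixture_inputs()
    else:
        inputs = _load_directory_inputs(Path(config["inputs"]["dir"]))

    sel_cfg = _selection_config(config)

    # --- stage 1: typing and representative selection
    typing, newick = _type_isolates(
        inputs["typing"], inputs["lanes"], config.get("rapd", {})
    )
    overrides = config.get("representative_override") or {}
    stage1 = step1_select(typing, representative_override=overrides)

    clusters = {
        p: list(sub["isolate_id"]) for p, sub in typing.groupby("rapd_pattern", sort=False)
    }
    rep_of = dict(zip(typing["rapd_pattern"], [None] * len(typing)))
    for rep in stage1:
        pattern = typing.loc[typing["isolate_id"] == rep, "rapd_pattern"].iloc[0]
        rep_of[pattern] = rep

    # --- stage 2: trait panel, binarization, per-species quota ranking
    if inputs["traits"] is not None:
        traits = inputs["traits"].set_index("strain_id")
        trait_key = {rep: rep for rep in stage1}
    else:
        derived = _derive_trait_table(inputs["assays"], clusters)
        traits = derived.set_index("assay_key")
        trait_key = {}
        for pattern, rep in rep_of.items():
            assayed = [m for m in clusters[pattern] if m in traits.index]
            if assayed:
                trait_key[rep] = assayed[0]

    panels = inputs["panels"]
    records = []
    panel_rows = []
    for rep in stage1:
        key = trait_key.get(rep)
        if key is None or key not in traits.index:
            raise ValidationError(f"no trait data for stage-1 strain {rep}")
        trow = traits.loc[key]
        panel_key = key if key in panels else rep
        if panel_key not in panels:
            raise ValidationError(f"no enzyme panel for strain {rep}")
        n_enzymes = enzyme_total(panels[panel_key])
        biomass = float(
            typing.loc[typing["isolate_id"] == rep, "biomass_g_per_L"].iloc[0]
        )
        species = str(typing.loc[typing["isolate_id"] == rep, "species"].iloc[0])
        panel = {
            "strain_id": rep,
            "species": species,
            "biomass_g_per_L": biomass,
            "enzyme_total": n_enzymes,
            "hemolysis": trow["hemolysis"],
            "halo_mm": trow["halo_mm"],
            "biofilm_od": trow["biofilm_od"],
            "autoaggregation_1h_pct": trow["autoaggregation_1h_pct"],
            "hydrophobicity_xylene_pct": trow["hydrophobicity_xylene_pct"],
        }
        records.append(binarize_traits(panel, sel_cfg))
        panel_rows.append(panel)

    stage2, stage2_rules = step2_select(records, sel_cfg)

    # --- stage 3: safety and stress vetting against the control group
    def endpoint_groups(df: pd.DataFrame, endpoint: float) -> GroupedMeasurements:
        labels, values = [], []
        for g, sub in df.groupby("group", sort=False):
            pcts = []
            for _, rep_sub in sub.groupby("replicate"):
                series = list(zip(rep_sub["hour"], rep_sub["alive"]))
                n0 = int(rep_sub["n0"].iloc[0])
                mean, _ = survival_percent([series], n0, endpoint)
                pcts.append(mean)
            labels.append(str(g))
            values.append(np.asarray(pcts))
        return GroupedMeasurements(labels, values, assay="survival", units="%")

    safety_end = float(inputs["safety"]["hour"].max())
    stress_end = float(inputs["stress"]["hour"].max())
    safety_groups = endpoint_groups(inputs["safety"], safety_end)
    stress_groups = endpoint_groups(inputs["stress"], stress_end)

    # map each stage-2 strain to the label it carries in the survival assays
    # (the assayed cluster member); strains never assayed in vivo cannot be
    # vetted and are retained with a note
    assayed = set(safety_groups.labels) & set(stress_groups.labels)
    surv_key = {}
    for s in stage2:
        if s in assayed:
            surv_key[s] = s
        elif trait_key.get(s) in assayed:
            surv_key[s] = trait_key[s]
    stage3_keys, stage3_report = step3_select(
        [surv_key[s] for s in stage2 if s in surv_key],
        safety_groups,
        stress_groups,
        seed=seed,
    )
    back = {v: k for k, v in surv_key.items()}
    stage3 = [back[k] for k in stage3_keys]
    stage3 += [s for s in stage2 if s not in surv_key]

    # omnibus biomass comparison across stage-2 strains, for the report
    stats_block: dict = {
        "safety_dunnett": stage3_report["safety"],
        "stress_dunnett": stage3_report["stress"],
    }
    if len(stage2) >= 2:
        biomass_groups = GroupedMeasurements(
            labels=[r.strain_id for r in records if r.strain_id in stage2],
            values=[
                np.asarray(
                    [r.biomass_g_per_L], dtype=float
                )  # single mean per strain in fixture mode
                for r in records
                if r.strain_id in stage2
            ],
            assay="biomass",
            units="g/L",
        )
        # only meaningful with replicate data; recorded as descriptive means
        stats_block["stage2_biomass_means"] = biomass_groups.means()

    # --- report assembly
    strain_table = pd.DataFrame(
        [
            {
                "strain_id": rep_of[p],
                "species": typing.loc[
                    typing["rapd_pattern"] == p, "species"
                ].iloc[0],
                "rapd_pattern": p,
                "n_members": len(members),
                "members": ",".join(members),
            }
            for p, members in clusters.items()
        ]
    )
    selection_rows = []
    for rec in records:
        selection_rows.append(
            {
                "strain_id": rec.strain_id,
                "species": rec.species,
                **{f"flag_{k}": int(v) for k, v in rec.flags.items()},
                "total": rec.total,
                "stage1": 1,
                "stage2": int(rec.strain_id in stage2),
                "stage3": int(rec.strain_id in stage3),
                "rule": stage2_rules.get(rec.strain_id, ""),
            }
        )
    selection = pd.DataFrame(selection_rows)

    counts = {
        "isolates": int(len(typing)),
        "stage1": len(stage1),
        "stage2": len(stage2),
        "stage3": len(stage3),
    }
    provenance = {
        "tool_version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "mode": mode,
        "stage_counts": counts,
        "final_selected": stage3,
    }
    bundle = ReportBundle(
        strain_table=strain_table,
        trait_panel=pd.DataFrame(panel_rows),
        selection=selection,
        stats=stats_block,
        newick=newick,
        provenance=provenance,
    )
    manifest = {"provenance": provenance}
    if out_dir is not None:
        manifest = write_report(bundle, out_dir)
    return bundle, manifest
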