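"""Domain types, delimited-table I/O, and packaged reference fixtures.

The screening study this package implements starts from 39 yeast isolates
cultured from the intestinal mucosa of healthy adult cobia. The packaged
fixtures transcribe the study's published tables: isolate identification
(sequencing calls plus a species-specific PCR for *Debaryomyces hansenii*),
RAPD pattern labels with dry-biomass production, the 19-enzyme API-ZYM
panel of the 16 dereplicated strains, and the binarized selection-criteria
grid. Quantities the study reports only graphically (biofilm OD,
autoaggregation and hydrophobicity percentages, larval survival replicates)
are shipped as clearly labelled ``*_synthetic.tsv`` stand-ins constructed to
match every reported classification and significance direction.

All tables are UTF-8, tab-separated, ``.`` decimal, header mandatory.
Missing measurements are empty cells and surface as ``None`` — never zero,
because zero is a legal measurement.
"""

from __future__ import annotations

import hashlib
import json
from collections import OrderedDict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "IsolateRecord",
    "StrainRecord",
    "AssayReplicate",
    "EnzymePanel",
    "IdentificationSummary",
    "ReportBundle",
    "API_ZYM_ENZYMES",
    "ENZYME_SCORES",
    "read_isolate_table",
    "read_typing_table",
    "read_enzyme_table",
    "read_trait_table",
    "read_survival_table",
    "summarize_identification",
    "write_report",
    "fixture_path",
    "load_fixture",
]


class SchemaError(ValueError):
    """A delimited file does not match its documented header schema."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant (bad enum, negative size...)."""


#: The 19 enzymes of the API-ZYM gallery, in gallery order (wells 2-20).
API_ZYM_ENZYMES = (
    "Alkaline phosphatase",
    "Esterase (C4)",
    "Esterase lipase (C8)",
    "Lipase (C14)",
    "Leucine arylamidase",
    "Valine arylamidase",
    "Cystine arylamidase",
    "Trypsin",
    "Alpha-chymotrypsin",
    "Acid phosphatase",
    "Naphthol-AS-BI-phosphohydrolase",
    "Alpha-galactosidase",
    "Beta-galactosidase",
    "Beta-glucuronidase",
    "Alpha-glucosidase",
    "Beta-glucosidase",
    "N-acetyl-beta-glucosaminidase",
    "Alpha-mannosidase",
    "Alpha-fucosidase",
)

ENZYME_SCORES = ("positive", "medium", "negative")
_SCORE_ALIASES = {
    "pos": "positive",
    "+": "positive",
    "med": "medium",
    "+-": "medium",
    "±": "medium",
    "neg": "negative",
    "-": "negative",
}

ORIGINS = ("CENAIM", "EMAGROCOM")
FEEDS = ("FF", "FFP")
PHYLA = ("Ascomycota", "Basidiomycota")
HEMOLYSIS_TYPES = ("alpha", "beta", "gamma")

#: Species-name -> phylum consistency map for the taxa seen in this dataset.
SPECIES_PHYLUM = {
    "Candida haemuloni": "Ascomycota",
    "Candida parapsilosis": "Ascomycota",
    "Debaryomyces hansenii": "Ascomycota",
    "Debaryomyces sp.": "Ascomycota",
    "Naganishia sp.": "Basidiomycota",
}


@dataclass(frozen=True)
class IsolateRecord:
    """One cultured colony: metadata plus its identification calls."""

    isolate_id: str
    fish_id: str
    origin: str
    feed: str
    species_sequence: str
    phylum: str
    species_specific_pcr: Optional[str] = None
    accession: Optional[str] = None

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValidationError(f"unknown origin {self.origin!r} for {self.isolate_id}")
        if self.feed not in FEEDS:
            raise ValidationError(f"unknown feed {self.feed!r} for {self.isolate_id}")
        if self.phylum not in PHYLA:
            raise ValidationError(f"unknown phylum {self.phylum!r} for {self.isolate_id}")
        expected = SPECIES_PHYLUM.get(self.species_sequence)
        if expected is not None and expected != self.phylum:
            raise ValidationError(
                f"{self.isolate_id}: species {self.species_sequence!r} is "
                f"{expected}, not {self.phylum}"
            )


@dataclass(frozen=True)
class StrainRecord:
    """A dereplicated strain: one representative isolate per RAPD pattern."""

    strain_id: str
    species: str
    rapd_pattern: str
    member_isolates: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.member_isolates:
            raise ValidationError(f"strain {self.strain_id}: no member isolates")
        if self.strain_id not in self.member_isolates:
            raise ValidationError(
                f"strain {self.strain_id}: representative not among members"
            )


@dataclass(frozen=True)
class AssayReplicate:
    """A single raw assay reading for one strain."""

    strain_id: str
    assay: str
    replicate_index: int
    value: float
    time: Optional[float] = None  # hours or days, assay-specific

    def __post_init__(self) -> None:
        if self.replicate_index < 1:
            raise ValidationError("replicate_index must be >= 1")


@dataclass
class EnzymePanel:
    """API-ZYM scores for one strain: 19 enzymes -> positive/medium/negative."""

    strain_id: str
    scores: "OrderedDict[str, str]"

    def __post_init__(self) -> None:
        if tuple(self.scores.keys()) != API_ZYM_ENZYMES:
            raise ValidationError(
                f"panel for {self.strain_id} must contain exactly the 19 "
                "API-ZYM enzymes in gallery order"
            )
        for enzyme, score in self.scores.items():
            if score not in ENZYME_SCORES:
                raise ValidationError(
                    f"{self.strain_id}/{enzyme}: bad score {score!r}"
                )


@dataclass
class IdentificationSummary:
    n_isolates: int
    by_species: dict
    by_phylum: dict
    by_origin: dict
    by_feed: dict
    phylum_pct: dict
    n_specific_pcr: dict

    @property
    def empty(self) -> bool:
        return self.n_isolates == 0


@dataclass
class ReportBundle:
    """Everything one pipeline run produces, ready for serialization."""

    strain_table: pd.DataFrame
    trait_panel: pd.DataFrame
    selection: pd.DataFrame  # long: strain_id, stage, selected, rule
    stats: dict
    newick: str = ""
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# readers


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_isolate_table(path) -> list[IsolateRecord]:
    """Read an isolate-identification table into validated records.

    Row order is preserved; isolate ids must be unique.
    """
    df = _read_tsv(path)
    _require_columns(
        df,
        ["isolate_id", "fish_id", "origin", "feed", "species_sequence", "phylum"],
        path,
    )
    records: list[IsolateRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = IsolateRecord(
                isolate_id=row.isolate_id,
                fish_id=row.fish_id,
                origin=row.origin,
                feed=row.feed,
                species_sequence=row.species_sequence,
                phylum=row.phylum,
                species_specific_pcr=getattr(row, "species_specific_pcr", "") or None,
                accession=getattr(row, "accession", "") or None,
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
        if rec.isolate_id in seen:
            raise ValidationError(f"{path} row {i}: duplicate isolate {rec.isolate_id}")
        seen.add(rec.isolate_id)
        records.append(rec)
    return records


def read_typing_table(path) -> pd.DataFrame:
    """Read the typing-and-biomass table (one row per isolate).

    Columns: isolate_id, species, biomass_g_per_L, biomass_se, rapd_pattern,
    selected (0/1). Numeric columns are parsed; empty cells become NaN.
    """
    df = _read_tsv(path)
    _require_columns(df, ["isolate_id", "species", "biomass_g_per_L"], path)
    out = df.copy()
    for col in ("biomass_g_per_L", "biomass_se"):
        if col in out.columns:
            out[col] = pd.to_numeric(out[col].replace("", None))
    if "selected" in out.columns:
        out["selected"] = pd.to_numeric(out["selected"]).astype(int)
    if out["isolate_id"].duplicated().any():
        dup = out.loc[out["isolate_id"].duplicated(), "isolate_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate isolate {dup}")
    return out


def read_enzyme_table(path) -> "OrderedDict[str, EnzymePanel]":
    """Read a wide enzyme grid (rows = enzymes, columns = strains)."""
    df = _read_tsv(path)
    _require_columns(df, ["enzyme"], path)
    enzymes = list(df["enzyme"])
    if tuple(enzymes) != API_ZYM_ENZYMES:
        raise SchemaError(
            f"{path}: enzyme rows must be the 19 API-ZYM enzymes in gallery order"
        )
    panels: "OrderedDict[str, EnzymePanel]" = OrderedDict()
    for strain in [c for c in df.columns if c != "enzyme"]:
        scores = OrderedDict()
        for enzyme, raw in zip(enzymes, df[strain]):
            score = _SCORE_ALIASES.get(raw, raw)
            scores[enzyme] = score
        panels[strain] = EnzymePanel(strain_id=strain, scores=scores)
    return panels


def read_trait_table(path) -> pd.DataFrame:
    """Read a per-strain trait panel (adhesion/safety assay summary)."""
    df = _read_tsv(path)
    _require_columns(df, ["strain_id", "hemolysis"], path)
    out = df.copy()
    for col in out.columns:
        if col.endswith(("_od", "_pct", "_mm")):
            out[col] = pd.to_numeric(out[col].replace("", None))
    bad = set(out["hemolysis"]) - set(HEMOLYSIS_TYPES)
    if bad:
        raise ValidationError(f"{path}: unknown hemolysis type(s) {sorted(bad)}")
    return out


def read_survival_table(path) -> pd.DataFrame:
    """Read long-format larval survival counts.

    Columns: group, replicate, hour, alive, n0. Counts must be non-increasing
    within each (group, replicate) series.
    """
    df = _read_tsv(path)
    _require_columns(df, ["group", "replicate", "hour", "alive", "n0"], path)
    out = df.copy()
    for col in ("replicate", "alive", "n0"):
        out[col] = pd.to_numeric(out[col]).astype(int)
    out["hour"] = pd.to_numeric(out["hour"])
    if (out["alive"] < 0).any() or (out["alive"] > out["n0"]).any():
        raise ValidationError(f"{path}: alive counts must satisfy 0 <= alive <= n0")
    for (grp, rep), sub in out.groupby(["group", "replicate"]):
        counts = sub.sort_values("hour")["alive"].to_numpy()
        if (counts[1:] > counts[:-1]).any():
            raise ValidationError(
                f"{path}: alive counts increase over time for {grp} replicate {rep}"
            )
    return out


# ---------------------------------------------------------------------------
# summaries


def summarize_identification(records: list[IsolateRecord]) -> IdentificationSummary:
    """Tabulate identification calls: counts and percentages per taxon/source.

    An empty record list yields an explicit empty summary rather than a crash.
    """
    if not records:
        return IdentificationSummary(0, {}, {}, {}, {}, {}, {})

    def count(key):
        out: dict = {}
        for r in records:
            out[key(r)] = out.get(key(r), 0) + 1
        return out

    by_phylum = count(lambda r: r.phylum)
    n = len(records)
    phylum_pct = {k: round(100.0 * v / n, 1) for k, v in by_phylum.items()}
    n_pcr = count(lambda r: r.species_specific_pcr)
    n_pcr.pop(None, None)
    return IdentificationSummary(
        n_isolates=n,
        by_species=count(lambda r: r.species_sequence),
        by_phylum=by_phylum,
        by_origin=count(lambda r: r.origin),
        by_feed=count(lambda r: r.feed),
        phylum_pct=phylum_pct,
        n_specific_pcr=n_pcr,
    )


# ---------------------------------------------------------------------------
# report serialization


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(bundle: ReportBundle, out_dir) -> dict:
    """Serialize a :class:`ReportBundle` to a deterministic file set.

    Returns a manifest mapping each written file to its SHA-256 checksum.
    Re-running with the same inputs and seed yields byte-identical numeric
    content (timestamps live only in provenance). On failure, any partially
    written files are removed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        for name, df in (
            ("strain_table.tsv", bundle.strain_table),
            ("trait_panel.tsv", bundle.trait_panel),
            ("selection.tsv", bundle.selection),
        ):
            p = out / name
            df.to_csv(p, sep="\t", index=False)
            written.append(p)
        p = out / "stats.json"
        p.write_text(json.dumps(bundle.stats, indent=2, sort_keys=True, default=str))
        written.append(p)
        p = out / "dendrogram.nwk"
        p.write_text(bundle.newick or "")
        written.append(p)
        manifest = {
            "files": {str(f.name): _sha256(f) for f in written},
            "provenance": bundle.provenance,
        }
        p = out / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
        written.append(p)
    except Exception:
        for f in written:
            f.unlink(missing_ok=True)
        raise
    return manifest


# ---------------------------------------------------------------------------
# packaged fixtures


def fixture_path(name: str):
    """Return a filesystem path to a packaged fixture table."""
    ref = resources.files("probioscreen") / "fixtures" / name
    return ref


def load_fixture(name: str) -> pd.DataFrame:
    with resources.as_file(fixture_path(name)) as p:
        return _read_tsv(p)
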