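"""Phenotypic trait derivation from raw assay readings.

Each function maps one raw assay to the screening metric used downstream:

* MATS hydrophobicity from paired absorbances, H% = (1 - A1/A0) x 100,
  classified low (< 20), medium (20-80) or high (> 80) against xylene;
* autoaggregation percent from standing-suspension absorbance decline,
  positive when strictly above 20%;
* crystal-violet biofilm score, producer when blank-corrected mean
  OD600 strictly exceeds 0.8;
* API-ZYM enzyme totals (medium and positive both count as active);
* hemolysis on blood agar (alpha/beta hemolytic, gamma safe);
* agar-well antagonism halo, positive when strictly wider than 1 mm;
* polyamine quantification through dansylated standard curves, in
  ng per mg yeast dry weight;
* growth-curve and storage-viability summaries, and endpoint larval
  survival percentages.

Thresholds are strict as stated unless a classification is explicitly
inclusive (the 20 and 80 endpoints fall in "medium" hydrophobicity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .data_model_io import EnzymePanel, HEMOLYSIS_TYPES, ValidationError

__all__ = [
    "StandardCurve",
    "PolyamineResult",
    "hydrophobicity_percent",
    "classify_hydrophobicity",
    "autoaggregation_percent",
    "autoaggregation_positive",
    "biofilm_score",
    "enzyme_total",
    "hemolysis_classify",
    "antagonism_positive",
    "fit_standard_curve",
    "polyamine_concentration",
    "growth_summary",
    "survival_percent",
    "mean_se",
]


def mean_se(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error of a replicate set (SE = 0 for one value)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("no replicate values")
    se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return float(v.mean()), se


def hydrophobicity_percent(a0: float, a1: float) -> float:
    """H% = (1 - A1/A0) x 100; A0 before solvent mixing, A1 aqueous after.

    Negative values (A1 > A0, possible under measurement noise) are returned
    as computed; the classifier maps them to "low".
    """
    if a0 <= 0:
        raise ZeroDivisionError("hydrophobicity: initial absorbance A0 must be > 0")
    if a1 < 0:
        raise ValidationError("hydrophobicity: A1 must be >= 0")
    return (1.0 - a1 / a0) * 100.0


def classify_hydrophobicity(h: float) -> str:
    """Classify xylene H% as low (< 20), medium (20-80) or high (> 80)."""
    if not np.isfinite(h):
        raise ValidationError("hydrophobicity value must be finite")
    if h > 80:
        return "high"
    if h >= 20:
        return "medium"
    return "low"


def autoaggregation_percent(a0: float, at: float) -> float:
    """[1 - A(t)/A(0)] x 100 for a standing suspension."""
    if a0 <= 0:
        raise ZeroDivisionError("autoaggregation: A0 must be > 0")
    if at < 0:
        raise ValidationError("autoaggregation: A(t) must be >= 0")
    return (1.0 - at / a0) * 100.0


def autoaggregation_positive(pct: float) -> bool:
    """Strictly more than 20% autoaggregation counts as positive."""
    return pct > 20.0


def biofilm_score(
    well_ods: Sequence[float], blank: float = 0.0, subtract_blank: bool = True
) -> tuple[float, bool]:
    """Mean blank-corrected crystal-violet OD600 and the producer call (> 0.8)."""
    ods = np.asarray(well_ods, dtype=float)
    if ods.size < 3:
        raise ValidationError("biofilm assay needs at least 3 replicate wells")
    if blank < 0:
        raise ValidationError("blank OD must be >= 0")
    corrected = ods - blank if subtract_blank else ods
    mean = float(corrected.mean())
    # strict threshold, guarded against float representation of the mean
    return mean, mean > 0.8 + 1e-9


def enzyme_total(panel: EnzymePanel) -> int:
    """Count active enzymes; medium and positive scores both count."""
    return sum(1 for s in panel.scores.values() if s in ("positive", "medium"))


def hemolysis_classify(observed: str) -> bool:
    """True (hemolytic) for alpha or beta lysis; gamma is nonhemolytic."""
    if observed not in HEMOLYSIS_TYPES:
        raise ValidationError(f"unknown hemolysis type {observed!r}")
    return observed in ("alpha", "beta")


def antagonism_positive(halo_mm: float) -> bool:
    """Inhibition halo strictly wider than 1 mm counts as antagonistic."""
    if halo_mm < 0:
        raise ValidationError("halo diameter must be >= 0")
    return halo_mm > 1.0


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares calibration of fluorescence peak area on analyte mass."""

    analyte: str
    slope: float  # peak-area per ng
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError(f"{self.analyte}: calibration slope must be > 0")


@dataclass(frozen=True)
class PolyamineResult:
    ng_per_mg: float
    below_lod: bool


def fit_standard_curve(series: Sequence[tuple[float, float]], analyte: str = "") -> StandardCurve:
    """OLS fit of peak area on mass (ng) for a dansylated standard series."""
    pts = np.asarray(series, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValidationError("standard curve needs >= 3 (ng, area) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 3:
        raise ValidationError("standard curve needs >= 3 distinct concentrations")
    if np.allclose(y, y[0]):
        raise ValidationError("constant peak areas: degenerate standard series")
    fit = stats.linregress(x, y)
    return StandardCurve(
        analyte=analyte,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def polyamine_concentration(
    peak_area: float,
    curve: StandardCurve,
    extract_volume_ml: float,
    dry_weight_mg: float,
) -> PolyamineResult:
    """Invert the standard curve and normalize to yeast dry weight.

    mass(ng per mL extract) = (area - intercept) / slope; the total mass in
    ``extract_volume_ml`` is divided by ``dry_weight_mg`` to give ng per mg
    dry weight. Areas at or below the intercept report 0 with a below-LOD
    flag rather than a negative concentration.
    """
    if dry_weight_mg <= 0:
        raise ValidationError("dry weight must be > 0")
    if extract_volume_ml <= 0:
        raise ValidationError("extract volume must be > 0")
    mass_ng = (peak_area - curve.intercept) / curve.slope
    if mass_ng <= 0:
        return PolyamineResult(0.0, below_lod=True)
    return PolyamineResult(mass_ng * extract_volume_ml / dry_weight_mg, below_lod=False)


def growth_summary(series: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """(t_max, A_max): the maximum OD600 and the earliest time it is reached."""
    pts = np.asarray(series, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValidationError("growth series needs >= 2 time points")
    t, a = pts[:, 0], pts[:, 1]
    if not (np.diff(t) > 0).all():
        raise ValidationError("growth series times must be strictly increasing")
    idx = int(np.argmax(a))  # argmax returns the earliest maximum
    return float(t[idx]), float(a[idx])


def survival_percent(
    alive_by_replicate: Sequence[Sequence[tuple[float, int]]],
    n0: int,
    endpoint_h: float,
) -> tuple[float, float]:
    """Endpoint survival, mean ± SE across replicate vessels.

    Each replicate is an (hour, alive) series; counts must be non-increasing
    and never exceed the starting number ``n0``. The endpoint percentage per
    replicate is 100 x alive(endpoint) / n0.
    """
    if n0 <= 0:
        raise ValidationError("n0 must be positive")
    endpoint_pcts = []
    for series in alive_by_replicate:
        pts = sorted((float(h), int(c)) for h, c in series)
        counts = [c for _, c in pts]
        if any(c > n0 or c < 0 for c in counts):
            raise ValidationError("alive counts must lie in [0, n0]")
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValidationError("alive counts must be non-increasing over time")
        at_end = [c for h, c in pts if h <= endpoint_h]
        if not at_end:
            raise ValidationError("no observation at or before the endpoint")
        endpoint_pcts.append(100.0 * at_end[-1] / n0)
    return mean_se(endpoint_pcts)
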