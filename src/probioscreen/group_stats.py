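"""Group comparison battery for replicate assay data.

The decision path mirrors common practice for small balanced assay designs:
check normality (Shapiro-Wilk, on pooled within-group residuals — per-group
samples of size 2-3 are too small to test alone) and homogeneity of variance
(Levene); if both hold run one-way ANOVA with Tukey HSD when the omnibus is
significant; if normality fails attempt a Johnson transformation
(S_B/S_L/S_U, percentile method) and re-test; otherwise fall back to
Kruskal-Wallis with Bonferroni-adjusted pairwise Mann-Whitney comparisons.
Every branch taken is recorded in the result.

Comparisons against a single control use Dunnett's many-to-one test. The
family-wise adjusted p-values are computed by seeded Monte Carlo on the
joint null distribution of the treatment-vs-control t statistics (correlated
multivariate t); the analytic lower bound p_adjusted >= p_unadjusted is
enforced exactly, and a Bonferroni p-value is reported as a conservative
cross-check.

Alpha is 0.05 throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .data_model_io import ValidationError

__all__ = [
    "GroupedMeasurements",
    "ComparisonResult",
    "DunnettResult",
    "choose_and_run",
    "dunnett_vs_control",
    "johnson_transform",
    "compact_letters",
]

ALPHA = 0.05


@dataclass
class GroupedMeasurements:
    """Replicate values per group (strain ids or "control")."""

    labels: list[str]
    values: list[np.ndarray]
    assay: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise ValidationError("labels and value groups must align")
        if len(self.labels) < 2:
            raise ValidationError("need at least 2 groups")
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        if any(v.size == 0 for v in self.values):
            raise ValidationError("every group needs at least one value")

    @classmethod
    def from_long(cls, df, group_col="group", value_col="value", **kw):
        labels, values = [], []
        for g, sub in df.groupby(group_col, sort=False):
            labels.append(str(g))
            values.append(sub[value_col].to_numpy(dtype=float))
        return cls(labels, values, **kw)

    def means(self) -> dict:
        return {l: float(v.mean()) for l, v in zip(self.labels, self.values)}


@dataclass
class ComparisonResult:
    method: str
    statistic: float
    p_value: float
    pairwise: dict  # (a, b) -> adjusted p
    letters: dict  # group -> letter string
    transformation: Optional[str] = None
    path: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass
class DunnettResult:
    control: str
    comparisons: dict  # group -> dict(t, p_unadjusted, p_adjusted, p_bonferroni, ...)

    def significantly_below(self) -> list[str]:
        return [
            g
            for g, c in self.comparisons.items()
            if c["p_adjusted"] < ALPHA and c["t"] < 0
        ]


# ---------------------------------------------------------------------------
# compact letter display


def compact_letters(groups: Sequence[str], significant_pairs: set) -> dict:
    """Assign letters so that two groups share a letter iff they are not
    separated by a significant pairwise difference (maximal-clique display).
    """
    groups = list(groups)
    k = len(groups)
    index = {g: i for i, g in enumerate(groups)}
    sig = {frozenset((index[a], index[b])) for a, b in significant_pairs}

    def is_clique(subset) -> bool:
        return all(
            frozenset((a, b)) not in sig for a, b in itertools.combinations(subset, 2)
        )

    cliques: list[tuple] = []
    # small k: enumerate maximal cliques directly
    for r in range(k, 0, -1):
        for subset in itertools.combinations(range(k), r):
            if not is_clique(subset):
                continue
            if any(set(subset) <= set(c) for c in cliques):
                continue
            cliques.append(subset)
    cliques.sort(key=lambda c: c[0])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for letter, clique in zip(alphabet, cliques):
        for i in clique:
            letters[groups[i]] += letter
    return letters


# ---------------------------------------------------------------------------
# Johnson transformation (percentile method)


def _johnson_candidates(x: np.ndarray, z: float):
    """Yield (name, transform array) for the S_B/S_L/S_U fits at fit point z."""
    probs = stats.norm.cdf([-3 * z, -z, z, 3 * z])
    x1, x2, x3, x4 = np.quantile(x, probs)
    m = x4 - x3
    n = x2 - x1
    p = x3 - x2
    if p <= 0 or m <= 0 or n <= 0:
        return

    # S_U: unbounded
    try:
        ratio = m * n / p**2
        if ratio > 1:
            eta = 2 * z / np.arccosh(0.5 * (m / p + n / p))
            gamma = eta * np.arcsinh((n / p - m / p) / (2 * np.sqrt(ratio - 1)))
            lam = (
                2
                * p
                * np.sqrt(ratio - 1)
                / ((m / p + n / p - 2) * np.sqrt(m / p + n / p + 2))
            )
            eps = (x3 + x2) / 2 + p * (n / p - m / p) / (2 * (m / p + n / p - 2))
            if lam > 0 and np.isfinite([eta, gamma, lam, eps]).all():
                y = gamma + eta * np.arcsinh((x - eps) / lam)
                if np.isfinite(y).all():
                    yield "SU", y
    except (FloatingPointError, ValueError):
        pass

    # S_B: bounded
    try:
        ratio = p**2 / (m * n)
        if ratio > 1:
            arg = 0.5 * np.sqrt((1 + p / m) * (1 + p / n))
            if arg > 1:
                eta = z / np.arccosh(arg)
                inner = (1 + p / m) * (1 + p / n) - 4
                if inner >= 0:
                    gamma = eta * np.arcsinh(
                        (p / n - p / m) * np.sqrt(inner) / (2 * (ratio - 1))
                    )
                    lam_inner = ((1 + p / m) * (1 + p / n) - 2) ** 2 - 4
                    if lam_inner >= 0:
                        lam = p * np.sqrt(lam_inner) / (ratio - 1)
                        eps = (
                            (x3 + x2) / 2
                            - lam / 2
                            + p * (p / n - p / m) / (2 * (ratio - 1))
                        )
                        if lam > 0 and (x > eps).all() and (x < eps + lam).all():
                            y = gamma + eta * np.log((x - eps) / (lam + eps - x))
                            if np.isfinite(y).all():
                                yield "SB", y
    except (FloatingPointError, ValueError):
        pass

    # S_L: lognormal boundary
    try:
        if m / p > 1:
            eta = 2 * z / np.log(m / p)
            eps = (x3 + x2) / 2 - (p / 2) * (m / p + 1) / (m / p - 1)
            if (x > eps).all():
                gamma = eta * np.log((m / p - 1) / (p * np.sqrt(m / p)))
                y = gamma + eta * np.log(x - eps)
                if np.isfinite(y).all():
                    yield "SL", y
    except (FloatingPointError, ValueError):
        pass


def johnson_transform(
    values: Sequence[float], z_grid: Sequence[float] = (0.25, 0.5, 0.75, 1.0, 1.25)
):
    """Normalize a sample by the best Johnson transformation.

    Fits S_B, S_L and S_U candidates by the percentile method over a grid of
    fit points and keeps the candidate maximizing the Shapiro-Wilk p-value
    of the transformed sample. Returns ``(transformed, family)`` where family
    is ``"identity"`` when no candidate improves normality. Requires at least
    8 observations; a constant sample is an error.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValidationError("Johnson transformation needs >= 8 observations")
    if np.allclose(x, x[0]):
        raise ValidationError("constant sample cannot be transformed")

    best_name, best_y, best_p = "identity", x, stats.shapiro(x).pvalue
    with np.errstate(all="ignore"):
        for z in z_grid:
            for name, y in _johnson_candidates(x, z):
                if np.allclose(y, y[0]):
                    continue
                p = stats.shapiro(y).pvalue
                if p > best_p:
                    best_name, best_y, best_p = name, y, p
    return best_y, best_name


# ---------------------------------------------------------------------------
# omnibus decision path


def _tukey_pairwise(groups: GroupedMeasurements, values: list[np.ndarray]) -> dict:
    res = stats.tukey_hsd(*values)
    out = {}
    for i, j in itertools.combinations(range(len(values)), 2):
        out[(groups.labels[i], groups.labels[j])] = float(res.pvalue[i, j])
    return out


def _mannwhitney_bonferroni(groups: GroupedMeasurements, values) -> dict:
    pairs = list(itertools.combinations(range(len(values)), 2))
    out = {}
    for i, j in pairs:
        try:
            p = stats.mannwhitneyu(values[i], values[j]).pvalue
        except ValueError:  # all values identical
            p = 1.0
        out[(groups.labels[i], groups.labels[j])] = min(1.0, float(p) * len(pairs))
    return out


def choose_and_run(
    data: GroupedMeasurements, alpha: float = ALPHA
) -> ComparisonResult:
    """Run the assumption-checked omnibus comparison and post-hoc display."""
    path: list[str] = []
    warnings: list[str] = []
    values = data.values
    transformation = None

    parametric_ok = all(v.size >= 2 for v in values)
    if not parametric_ok:
        warnings.append("group with < 2 replicates: nonparametric path forced")

    def assumptions_hold(vals) -> bool:
        residuals = np.concatenate([v - v.mean() for v in vals])
        sw_p = stats.shapiro(residuals).pvalue
        path.append(f"shapiro_wilk p={sw_p:.4g}")
        if sw_p <= alpha:
            return False
        lev_p = stats.levene(*vals).pvalue
        path.append(f"levene p={lev_p:.4g}")
        return lev_p > alpha

    if parametric_ok and assumptions_hold(values):
        path.append("one_way_anova")
        stat, p = stats.f_oneway(*values)
        pairwise = _tukey_pairwise(data, values) if p < alpha else {}
        method = "anova_tukey"
    else:
        transformed = None
        if parametric_ok:
            pooled = np.concatenate(values)
            if pooled.size >= 8 and not np.allclose(pooled, pooled[0]):
                y, family = johnson_transform(pooled)
                if family != "identity":
                    # re-split the transformed pooled sample into groups
                    splits = np.cumsum([v.size for v in values])[:-1]
                    candidate = np.split(y, splits)
                    path.append(f"johnson_{family}")
                    if assumptions_hold(candidate):
                        transformed = candidate
                        transformation = family
        if transformed is not None:
            path.append("one_way_anova_on_transformed")
            stat, p = stats.f_oneway(*transformed)
            pairwise = _tukey_pairwise(data, transformed) if p < alpha else {}
            method = "johnson_anova_tukey"
        else:
            path.append("kruskal_wallis")
            try:
                stat, p = stats.kruskal(*values)
            except ValueError:  # all values identical across groups
                stat, p = 0.0, 1.0
            pairwise = _mannwhitney_bonferroni(data, values) if p < alpha else {}
            method = "kruskal_bonferroni"

    sig_pairs = {pair for pair, padj in pairwise.items() if padj < alpha}
    letters = compact_letters(data.labels, sig_pairs)
    return ComparisonResult(
        method=method,
        statistic=float(stat),
        p_value=float(p),
        pairwise=pairwise,
        letters=letters,
        transformation=transformation,
        path=path,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Dunnett many-to-one


def dunnett_vs_control(
    data: GroupedMeasurements,
    control_label: str = "control",
    n_mc: int = 100_000,
    seed: int = 0,
    alpha: float = ALPHA,
) -> DunnettResult:
    """Two-sided Dunnett comparisons of every treatment against the control.

    The family-wise adjusted p-value of treatment i is
    P(max_j |T_j| >= |t_i|) under the joint null, estimated from ``n_mc``
    seeded Monte Carlo draws of the correlated treatment-vs-control t
    statistics (shared control mean and shared pooled variance).
    """
    if control_label not in data.labels:
        raise ValidationError(f"control group {control_label!r} missing")
    ctrl_idx = data.labels.index(control_label)
    treat_idx = [i for i in range(len(data.labels)) if i != ctrl_idx]
    if any(v.size < 2 for v in data.values):
        raise ValidationError("Dunnett needs >= 2 replicates per group")

    ns = np.array([v.size for v in data.values])
    means = np.array([v.mean() for v in data.values])
    df = int(ns.sum() - len(ns))
    ss = sum(float(((v - v.mean()) ** 2).sum()) for v in data.values)
    s2 = ss / df
    if s2 == 0:
        s2 = np.finfo(float).tiny  # all replicates identical: t -> 0 or inf

    scale = np.sqrt(s2 * (1.0 / ns[treat_idx] + 1.0 / ns[ctrl_idx]))
    t_obs = (means[treat_idx] - means[ctrl_idx]) / scale

    rng = np.random.default_rng(seed)
    z_t = rng.standard_normal((n_mc, len(treat_idx))) / np.sqrt(ns[treat_idx])
    z_c = rng.standard_normal((n_mc, 1)) / np.sqrt(ns[ctrl_idx])
    v = rng.chisquare(df, size=(n_mc, 1)) / df
    t_null = (z_t - z_c) / np.sqrt(v * (1.0 / ns[treat_idx] + 1.0 / ns[ctrl_idx]))
    max_abs = np.abs(t_null).max(axis=1)

    comparisons = {}
    k = len(treat_idx)
    for t, idx in zip(t_obs, treat_idx):
        p_un = float(2 * stats.t.sf(abs(t), df))
        p_mc = float((max_abs >= abs(t)).mean())
        p_adj = max(p_mc, p_un)  # analytic bound: max|T| >= |T_i| pointwise
        comparisons[data.labels[idx]] = {
            "t": float(t),
            "df": df,
            "p_unadjusted": p_un,
            "p_adjusted": p_adj,
            "p_bonferroni": min(1.0, k * p_un),
            "significant": p_adj < alpha,
            "direction": "below" if t < 0 else "above",
        }
    return DunnettResult(control=control_label, comparisons=comparisons)
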