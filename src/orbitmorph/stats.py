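"""Between-group inference and effect sizes for orbital dimensions.

Conventions used throughout:

* eta-squared (one-way ANOVA effect size) is SSB / (SSB + SSW);
* the rank-biserial correlation for a Mann-Whitney comparison is
  ``r_rb = 2U/(n_x n_y) - 1`` with U counted for the first sample, so a
  positive value means the first sample is stochastically larger;
* Spearman's rho is the Pearson correlation of midranks with a
  t-approximation p-value;
* pairwise post hoc comparisons are Welch t tests with Bonferroni
  adjustment (``p_adj = min(1, m * p)``) — the studentized-range (Tukey
  HSD) quantiles are deliberately not used here.

``mixture_eta_squared`` gives the analytic eta-squared implied by a
finite mixture of per-type distributions, either straight from tabulated
per-type means/SDs or with moments adjusted for range truncation, for
checking simulated cohorts against their generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .synthetic_data import DIMENSIONS, MorphotypeParameters

__all__ = [
    "GroupComparisonResult",
    "anova_eta2",
    "kruskal_wallis",
    "mann_whitney_rb",
    "spearman_rho",
    "pairwise_posthoc",
    "mixture_eta_squared",
    "AGE_GROUP_BINS",
    "assign_age_groups",
]

#: fixed age strata (years): juvenile/young adult, middle, older
AGE_GROUP_BINS = ((8, 30), (31, 55), (56, 88))


@dataclass(frozen=True)
class GroupComparisonResult:
    """One inferential comparison: statistic, p, and effect size."""

    name: str
    statistic: float
    p_value: float
    df: Optional[tuple] = None
    effect_size: Optional[float] = None
    effect_name: Optional[str] = None
    group_labels: tuple = ()
    group_sizes: tuple = ()
    extras: dict = field(default_factory=dict)


def _as_groups(groups: Sequence) -> list:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    return out


def anova_eta2(groups: Sequence, labels: Optional[Sequence[str]] = None) -> GroupComparisonResult:
    """One-way ANOVA with eta-squared.

    ``F = (SSB/df_b) / (SSW/df_w)`` and ``eta2 = SSB / (SSB + SSW)``;
    the p-value comes from the F distribution with (k-1, n-k) df.
    """
    gs = _as_groups(groups)
    if any(len(g) < 2 for g in gs):
        raise ValueError("every group needs at least 2 values")
    sizes = np.array([len(g) for g in gs])
    n, k = sizes.sum(), len(gs)
    grand = np.concatenate(gs).mean()
    ssb = float(sum(len(g) * (g.mean() - grand) ** 2 for g in gs))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    if ssb + ssw <= 0:
        raise ValueError("zero total variance: ANOVA undefined")
    df_b, df_w = k - 1, n - k
    if ssw == 0:
        F, p = np.inf, 0.0
    else:
        F = (ssb / df_b) / (ssw / df_w)
        p = float(sps.f.sf(F, df_b, df_w))
    return GroupComparisonResult(
        name="one-way ANOVA",
        statistic=float(F),
        p_value=p,
        df=(df_b, int(df_w)),
        effect_size=ssb / (ssb + ssw),
        effect_name="eta_squared",
        group_labels=tuple(labels) if labels else tuple(range(k)),
        group_sizes=tuple(int(s) for s in sizes),
        extras={"ssb": ssb, "ssw": ssw},
    )


def kruskal_wallis(groups: Sequence, labels: Optional[Sequence[str]] = None) -> GroupComparisonResult:
    """Kruskal-Wallis H with midrank tie correction, chi-square p (k-1 df)."""
    gs = _as_groups(groups)
    if any(len(g) == 0 for g in gs):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(gs)
    if pooled.size < 3:
        raise ValueError("need at least 3 values in total")
    if np.all(pooled == pooled[0]):
        raise ValueError("all values identical: H undefined without variance")
    H, p = sps.kruskal(*gs)
    return GroupComparisonResult(
        name="Kruskal-Wallis",
        statistic=float(H),
        p_value=float(p),
        df=(len(gs) - 1,),
        group_labels=tuple(labels) if labels else tuple(range(len(gs))),
        group_sizes=tuple(len(g) for g in gs),
    )


def mann_whitney_rb(
    x: Sequence, y: Sequence, exact_max_product: int = 400
) -> GroupComparisonResult:
    """Mann-Whitney U with the rank-biserial correlation.

    U is computed from midranks.  The p-value uses the exact null
    distribution when the samples are tie-free and ``n_x * n_y`` is at
    most *exact_max_product*, otherwise the normal approximation with
    tie correction.  ``r_rb = 2U/(n_x n_y) - 1`` is oriented so that a
    positive value means x is stochastically larger than y.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < nx + ny
    method = "exact" if (nx * ny <= exact_max_product and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    U = float(res.statistic)  # U for x, built from midranks
    r_rb = 2.0 * U / (nx * ny) - 1.0
    return GroupComparisonResult(
        name="Mann-Whitney U",
        statistic=U,
        p_value=float(res.pvalue),
        effect_size=r_rb,
        effect_name="rank_biserial",
        group_sizes=(nx, ny),
        extras={"method": method},
    )


def spearman_rho(x: Sequence, y: Sequence) -> GroupComparisonResult:
    """Spearman rank correlation (Pearson on midranks, t-approximation p)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return GroupComparisonResult(
        name="Spearman rho",
        statistic=float(rho),
        p_value=float(p),
        effect_size=float(rho),
        effect_name="spearman_rho",
        group_sizes=(len(x),),
    )


def pairwise_posthoc(
    groups: Sequence,
    labels: Optional[Sequence[str]] = None,
    method: str = "bonferroni_welch",
) -> list:
    """All pairwise Welch t tests, optionally Bonferroni-adjusted.

    ``method="bonferroni_welch"`` multiplies each raw p by the number of
    pairs (capped at 1); ``method="none"`` reports raw p-values.
    """
    if method not in ("bonferroni_welch", "none"):
        raise ValueError(f"unknown method {method!r}")
    gs = _as_groups(groups)
    if any(len(g) < 2 for g in gs):
        raise ValueError("every group needs at least 2 values")
    labels = tuple(labels) if labels else tuple(range(len(gs)))
    pairs = list(combinations(range(len(gs)), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        t, p = sps.ttest_ind(gs[i], gs[j], equal_var=False)
        p_adj = min(1.0, m * float(p)) if method == "bonferroni_welch" else float(p)
        out.append(
            GroupComparisonResult(
                name="Welch t (pairwise)",
                statistic=float(t),
                p_value=p_adj,
                group_labels=(labels[i], labels[j]),
                group_sizes=(len(gs[i]), len(gs[j])),
                extras={"p_raw": float(p), "n_comparisons": m},
            )
        )
    return out


def mixture_eta_squared(
    params: Sequence[MorphotypeParameters],
    dimension: str,
    truncation_adjusted: bool = False,
) -> float:
    """Analytic eta-squared of one dimension under the three-type mixture.

    With component means m_k, variances v_k and weights p_k,

        eta2 = sum p_k (m_k - m)^2 / (sum p_k (m_k - m)^2 + sum p_k v_k)

    which is the large-n limit of SSB/(SSB+SSW) for a cohort drawn from
    the mixture.  By default the tabulated per-type mean/SD are used
    as-is (they are the empirical within-type moments); with
    ``truncation_adjusted=True`` the moments of the range-truncated
    normal are used instead, matching what the rejection-sampling
    generator actually produces.
    """
    if dimension not in DIMENSIONS:
        raise KeyError(f"unknown dimension {dimension!r}; expected one of {DIMENSIONS}")
    w = np.array([p.prevalence for p in params])
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("prevalences must sum to 1")
    means, variances = [], []
    for p in params:
        d = p.dimension(dimension)
        if truncation_adjusted:
            a, b = (d.minimum - d.mean) / d.sd, (d.maximum - d.mean) / d.sd
            m, v = sps.truncnorm.stats(a, b, loc=d.mean, scale=d.sd, moments="mv")
            means.append(float(m))
            variances.append(float(v))
        else:
            means.append(d.mean)
            variances.append(d.sd**2)
    means = np.array(means)
    variances = np.array(variances)
    grand = float(w @ means)
    between = float(w @ (means - grand) ** 2)
    within = float(w @ variances)
    return between / (between + within)


def assign_age_groups(ages: Sequence) -> np.ndarray:
    """Label ages with the fixed strata 8-30, 31-55, 56-88 years.

    Ages outside every stratum come back as the empty string.
    """
    ages = np.asarray(ages, dtype=float)
    out = np.full(ages.shape, "", dtype=object)
    for lo, hi in AGE_GROUP_BINS:
        out[(ages >= lo) & (ages <= hi)] = f"{lo}-{hi}"
    return out
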