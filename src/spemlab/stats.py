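"""Group-level statistics for cohort index tables.

With nine subjects per group the analysis is deliberately non-parametric:
a Lilliefors-style Kolmogorov-Smirnov check of normality (Monte-Carlo null,
because the plain KS null is wrong when mean and SD are estimated from the
sample), a Wilcoxon-Mann-Whitney rank test for group differences, and
Hedges' g as a small-sample-corrected standardized effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .cohort import CohortTable

__all__ = [
    "GroupComparison",
    "ks_normality",
    "mann_whitney",
    "hedges_g",
    "summarize_cohort",
]


@dataclass(frozen=True)
class GroupComparison:
    measure: str
    sz_mean: float
    cnt_mean: float
    u_statistic: float
    p_value: float
    hedges_g: float
    significant: bool


def _ks_distance_fitted(sample: np.ndarray) -> float:
    """KS distance of a sample to the normal fitted to it (mean, sd ddof=1)."""
    n = sample.size
    z = np.sort((sample - sample.mean()) / sample.std(ddof=1))
    cdf = special.ndtr(z)
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - cdf, cdf - (i - 1) / n)))


def ks_normality(
    sample, n_mc: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality check with estimated parameters.

    The KS distance is computed against a normal with the sample's own mean
    and SD; since that fitted null shrinks the distance, the p-value comes
    from a seeded Monte-Carlo (Lilliefors) null: ``n_mc`` standard-normal
    samples of the same size, each tested against its own fitted normal.
    Returns ``(distance, p)`` with ``p = (1 + #{D_mc >= D}) / (1 + n_mc)``.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if x.std(ddof=1) == 0:
        raise ValueError("zero-variance sample")
    d_obs = _ks_distance_fitted(x)

    rng = np.random.default_rng(seed)
    n = x.size
    draws = rng.standard_normal((n_mc, n))
    draws = (draws - draws.mean(axis=1, keepdims=True)) / draws.std(
        axis=1, ddof=1, keepdims=True
    )
    z = np.sort(draws, axis=1)
    cdf = special.ndtr(z)
    i = np.arange(1, n + 1)
    d_null = np.max(np.maximum(i / n - cdf, cdf - (i - 1) / n), axis=1)
    p = (1 + int(np.count_nonzero(d_null >= d_obs))) / (1 + n_mc)
    return d_obs, float(p)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Returns ``(U, p)`` with U the rank-sum statistic of the first sample
    (midranks for ties), so swapping groups maps U to n_a*n_b - U with the
    same p.  The p-value is the exact permutation tail when the pooled
    sample is small (n_a + n_b <= 20) and tie-free, else the normal
    approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def hedges_g(a, b) -> float:
    """Hedges' g of group b over group a (positive when mean(b) > mean(a)).

    ``g = J * (mean_b - mean_a) / s_pooled`` with the pooled SD from unbiased
    group variances and the small-sample correction
    ``J = 1 - 3 / (4*(n_a + n_b) - 9)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    s_pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if s_pooled == 0:
        raise ValueError("zero pooled standard deviation")
    j = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float(j * (b.mean() - a.mean()) / s_pooled)


def summarize_cohort(
    table: CohortTable, alpha: float = 0.05, holm: bool = False
) -> pd.DataFrame:
    """Per-measure group comparison of a cohort table.

    For every measure: group means, Mann-Whitney U (SZ as first group) and
    two-sided p, Hedges' g (positive when CNT exceeds SZ) and a significance
    flag at ``alpha``.  No multiple-testing correction by default; ``holm``
    applies a Holm step-down over the measures.
    """
    rows = []
    for measure in table.measures:
        sz, cnt = table.group_values(measure)
        u, p = mann_whitney(sz, cnt)
        try:
            g = hedges_g(sz, cnt)
        except ValueError:
            g = np.nan
        rows.append(
            {
                "measure": measure,
                "sz_mean": float(sz.mean()),
                "cnt_mean": float(cnt.mean()),
                "u_statistic": u,
                "p_value": p,
                "hedges_g": g,
            }
        )
    out = pd.DataFrame(rows)
    if holm:
        order = np.argsort(out["p_value"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p_value"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_adjusted"] = adj
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    return out
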