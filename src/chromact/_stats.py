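"""Shared statistical primitives.

Thin wrappers over scipy/statsmodels so that every enrichment and rank
test in the package goes through one audited code path.  Conventions:
Fisher two-sided p sums probabilities of tables no more likely than the
observed one; rank-sum tests are exact for small samples and use the
tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 exact-test output used by every enrichment claim."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    n_x: int
    n_y: int
    median_x: float
    median_y: float


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def poisson_upper_tail(k: np.ndarray | int, lam: np.ndarray | float) -> np.ndarray:
    """P(X >= k) for X ~ Poisson(lam); equals 1 when k <= 0."""
    k = np.asarray(k)
    return stats.poisson.sf(k - 1, lam)


def fisher_exact_2x2(table) -> ContingencyResult:
    """Two-sided Fisher exact test on a 2x2 count table."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 table")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return ContingencyResult(
        ((int(t[0, 0]), int(t[0, 1])), (int(t[1, 0]), int(t[1, 1]))),
        float(odds),
        float(p),
    )


def rank_sum_test(x, y, exact_max: int = 20) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null enumeration when both samples have at most ``exact_max``
    observations and there are no ties; tie-corrected normal
    approximation (with continuity correction) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test needs two non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= exact_max and y.size <= exact_max and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return RankTestResult(
        float(res.statistic), float(res.pvalue),
        int(x.size), int(y.size),
        float(np.median(x)), float(np.median(y)),
    )


def pearson_log(x, y, pseudocount: float = 0.5) -> tuple[float, float]:
    """Pearson r and p on log2(value + pseudocount)."""
    x = np.log2(np.asarray(x, dtype=float) + pseudocount)
    y = np.log2(np.asarray(y, dtype=float) + pseudocount)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def poisson_two_sample(k1: int, k2: int, ratio: float = 1.0) -> float:
    """Exact two-sided test of H0: rate1/rate2 == ratio for two Poisson
    counts, via the conditional binomial: given n = k1 + k2,
    k1 ~ Binomial(n, ratio / (1 + ratio)) under H0."""
    n = k1 + k2
    if n == 0:
        return 1.0
    p0 = ratio / (1.0 + ratio)
    return float(stats.binomtest(k1, n, p0, alternative="two-sided").pvalue)
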