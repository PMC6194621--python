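"""Rank-based hypothesis tests for group comparisons.

Two-sample comparisons (innovator brand vs generic baskets) use the Wilcoxon
rank-sum test; the three-region comparison uses the Kruskal-Wallis k-sample
rank test.  Ties receive midranks.  The two-sample p-value is exact (by
enumeration of rank assignments) for small tie-free samples and otherwise a
normal approximation with tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["TestResult", "wilcoxon_rank_sum", "k_sample_rank_test"]

EXACT_THRESHOLD = 12
ALTERNATIVES = ("two_sided", "less", "greater")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str                     # "exact" | "normal_approx"
    group_sizes: tuple[int, ...]
    alternative: str = "two_sided"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _tie_term(pooled_ranks: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(pooled_ranks, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _exact_rank_sum_p(w: float, n1: int, n2: int, alternative: str) -> float:
    """Exact null distribution of the rank sum by enumerating C(n, n1) splits."""
    n = n1 + n2
    total = comb(n, n1)
    sums = np.fromiter(
        (sum(c) for c in combinations(range(1, n + 1), n1)),
        dtype=float, count=total,
    )
    p_le = np.count_nonzero(sums <= w + 1e-9) / total
    p_ge = np.count_nonzero(sums >= w - 1e-9) / total
    if alternative == "less":
        return p_le
    if alternative == "greater":
        return p_ge
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
    exact_threshold: int = EXACT_THRESHOLD,
    continuity: bool = True,
) -> TestResult:
    """Wilcoxon rank-sum test of whether ``x`` tends to exceed ``y``.

    The statistic is the sum of midranks of ``x`` in the pooled sample.
    Exact enumeration is used when ``len(x) + len(y) <= exact_threshold`` and
    the pooled data is tie-free; otherwise a normal approximation with tie
    correction and (by default) a 0.5 continuity correction.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)          # midranks for ties
    w = float(ranks[:n1].sum())
    has_ties = np.unique(pooled).size < n

    if n <= exact_threshold and not has_ties:
        p = _exact_rank_sum_p(w, n1, n2, alternative)
        return TestResult(w, p, "exact", (n1, n2), alternative)

    mean = n1 * (n + 1) / 2.0
    tie = _tie_term(pooled)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:                            # all observations identical
        return TestResult(w, 1.0, "normal_approx", (n1, n2), alternative)
    sd = np.sqrt(var)
    cc = 0.5 if continuity else 0.0
    if alternative == "greater":
        p = stats.norm.sf((w - mean - cc) / sd)
    elif alternative == "less":
        p = stats.norm.cdf((w - mean + cc) / sd)
    else:
        z = (abs(w - mean) - cc) / sd
        p = 2.0 * stats.norm.sf(max(z, 0.0))
    return TestResult(w, float(min(p, 1.0)), "normal_approx", (n1, n2), alternative)


def k_sample_rank_test(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis test that k groups share one location.

    H (tie-corrected) is referred to a chi-square with k-1 degrees of
    freedom.  For k = 2 the p-value agrees with the two-sided Wilcoxon
    normal approximation without continuity correction.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start:start + a.size]
        h += r.sum() ** 2 / a.size
        start += a.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    if correction <= 0:                     # every observation identical
        return TestResult(0.0, 1.0, "normal_approx", tuple(a.size for a in arrays))
    h /= correction
    p = float(stats.chi2.sf(h, df=len(arrays) - 1))
    return TestResult(float(h), p, "normal_approx", tuple(a.size for a in arrays))
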