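"""Nonparametric testing layer.

Thin, contract-checked wrappers around the standard tests used throughout
the analysis (Fisher's exact, Wilcoxon rank-sum and signed-rank,
Kruskal-Wallis with Dunn-Sidak post hoc) plus a Friedman test with a
Nemenyi critical-difference post hoc, which has no scipy implementation.
The Nemenyi critical difference uses the studentized-range quantile at
infinite degrees of freedom:

    CD = q_alpha / sqrt(2) * sqrt(k (k + 1) / (6 n))

for k conditions and n subjects; two conditions differ when their mean
within-subject ranks differ by more than CD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "fisher_2x2",
    "rank_sum",
    "signed_rank",
    "kruskal_dunn_sidak",
    "friedman_nemenyi",
    "nemenyi_critical_difference",
]

ALPHA = 0.05


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    n: tuple
    posthoc: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def fisher_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Degenerate tables (any zero margin) carry no information about
    association; p = 1 by convention, with a warning.
    """
    cells = (a, b, c, d)
    if any(x < 0 or int(x) != x for x in cells):
        raise ValueError("cell counts must be non-negative integers")
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("zero margin in 2x2 table; p = 1 by convention")
        return TestResult("fisher_exact", np.nan, 1.0, cells)
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return TestResult("fisher_exact", float(odds), float(p), cells)


def _all_tied(*samples) -> bool:
    allv = np.concatenate([np.asarray(s, float).ravel() for s in samples])
    return bool(np.all(allv == allv[0]))


def rank_sum(x, y) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test, normal approximation with
    tie correction."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if _all_tied(x, y):
        warnings.warn("all observations tied; p = 1")
        return TestResult("rank_sum", np.nan, 1.0, (x.size, y.size))
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult("rank_sum", float(res.statistic), float(res.pvalue), (x.size, y.size))


def signed_rank(x, y=None) -> TestResult:
    """Wilcoxon signed-rank test for matched pairs (or one sample vs 0)."""
    x = np.asarray(x, float)
    d = x - np.asarray(y, float) if y is not None else x
    if np.all(d == 0):
        warnings.warn("all differences zero; p = 1")
        return TestResult("signed_rank", np.nan, 1.0, (d.size,))
    res = sps.wilcoxon(d, zero_method="wilcox", method="approx")
    return TestResult("signed_rank", float(res.statistic), float(res.pvalue), (d.size,))


def kruskal_dunn_sidak(*groups, alpha: float = ALPHA) -> TestResult:
    """Kruskal-Wallis omnibus test; Dunn's pairwise z-tests with Sidak
    correction are attached only when the omnibus test is significant."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, float) for g in groups]
    ns = tuple(g.size for g in groups)
    if _all_tied(*groups):
        warnings.warn("all observations tied; p = 1")
        return TestResult("kruskal_wallis", 0.0, 1.0, ns)
    stat, p = sps.kruskal(*groups)
    posthoc = None
    if p < alpha:
        posthoc = _dunn_sidak(groups)
    return TestResult("kruskal_wallis", float(stat), float(p), ns, posthoc)


def _dunn_sidak(groups) -> pd.DataFrame:
    allv = np.concatenate(groups)
    ranks = sps.rankdata(allv)
    n_total = allv.size
    # tie correction for the rank variance
    _, counts = np.unique(allv, return_counts=True)
    tie = np.sum(counts**3 - counts) / (12.0 * (n_total - 1))
    splits = np.cumsum([g.size for g in groups])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = [r.mean() for r in group_ranks]
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie)
            * (1.0 / groups[i].size + 1.0 / groups[j].size)
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = 1.0 - (1.0 - min(p_raw, 1.0)) ** m
        rows.append({"i": i, "j": j, "z": z, "p_raw": p_raw, "p_sidak": p_adj,
                     "significant": p_adj < ALPHA})
    return pd.DataFrame(rows)


def nemenyi_critical_difference(k: int, n: int, alpha: float = ALPHA) -> float:
    """Nemenyi CD for k conditions and n subjects at level alpha."""
    q = sps.studentized_range.ppf(1.0 - alpha, k, 1e8)
    return float(q / np.sqrt(2.0) * np.sqrt(k * (k + 1) / (6.0 * n)))


def friedman_nemenyi(matrix, alpha: float = ALPHA) -> TestResult:
    """Friedman test over a subjects x conditions matrix with Nemenyi
    post hoc.

    The post-hoc table (pairwise mean-rank differences vs the critical
    difference) is attached only when the omnibus test is significant.
    Missing cells are an error: the test needs complete repeated measures.
    """
    m = np.asarray(matrix, float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a subjects x conditions matrix, both >= 2")
    if np.isnan(m).any():
        raise ValueError("missing cells are not allowed")
    n, k = m.shape
    ranks = sps.rankdata(m, axis=1)
    mean_ranks = ranks.mean(axis=0)
    if np.allclose(m, m[:, [0]]):
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.friedmanchisquare(*(m[:, j] for j in range(k)))
    posthoc = None
    if p < alpha:
        cd = nemenyi_critical_difference(k, n, alpha)
        rows = [
            {
                "i": i, "j": j,
                "rank_diff": abs(mean_ranks[i] - mean_ranks[j]),
                "critical_difference": cd,
                "significant": abs(mean_ranks[i] - mean_ranks[j]) > cd,
            }
            for i, j in combinations(range(k), 2)
        ]
        posthoc = pd.DataFrame(rows)
    return TestResult("friedman", float(stat), float(p), (n, k), posthoc)
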