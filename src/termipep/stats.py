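"""Wilcoxon rank-sum testing, null calibration and multiplicity accounting.

Caste comparisons here rest on the two-sample Wilcoxon (Mann-Whitney)
rank-sum test.  The exact two-sided p-value is the proportion of all
C(n1+n2, n1) relabelings of the pooled observations whose group-1 rank sum
W is at least as far from its null mean E0[W] = n1 (n1+n2+1)/2 as the
observed one; ties are handled by mid-ranks, and the enumeration runs over
the observed pooled multiset.  The full permutation distribution is
computed with an exact subset-sum recursion over doubled mid-ranks (so
half-integer mid-ranks become integers), which enumerates the same
distribution as listing every assignment but is feasible at n1 = n2 = 15
where there are ~1.55e8 assignments.

A normal approximation with tie-corrected variance and continuity
correction is provided for larger groups, and a seeded null-calibration
routine quantifies the multiple-testing burden: 100 independent null tests
are expected to produce about five p < 0.05 results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps


@dataclass
class RankTestResult:
    W: float                # rank sum of group 1 (mid-ranks)
    n1: int
    n2: int
    p_two_sided: float
    method: str             # "exact" | "normal_tie_corrected"
    ties: tuple[int, ...]   # multiplicities of tied pooled values
    degenerate: bool = False


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _tie_profile(pooled: np.ndarray) -> tuple[int, ...]:
    _, counts = np.unique(pooled, return_counts=True)
    return tuple(int(c) for c in counts)


@lru_cache(maxsize=4096)
def _ranksum_distribution(ranks2: tuple[int, ...], n1: int) -> np.ndarray:
    """Exact counts of n1-subsets of ``ranks2`` (doubled mid-ranks) by sum.

    Returns an array D where D[s] = number of n1-subsets with doubled rank
    sum s.  Equivalent to exhaustively enumerating all C(N, n1) group
    assignments.
    """
    total = sum(ranks2)
    # dp[j][s]: subsets of size j with doubled sum s
    dp = np.zeros((n1 + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in ranks2:
        for j in range(n1, 0, -1):
            dp[j, r:] += dp[j - 1, :total + 1 - r]
    return dp[n1]


def wilcoxon_exact(x, y) -> RankTestResult:
    """Exact two-sided Wilcoxon rank-sum test by full enumeration.

    Intended for n1 + n2 <= 30; beyond that use :func:`wilcoxon_approx`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    N = n1 + n2
    if N > 30:
        raise ValueError("exact enumeration restricted to n1 + n2 <= 30")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    ranks2 = tuple(int(round(2 * r)) for r in ranks)
    w_obs2 = int(round(2 * ranks[:n1].sum()))
    e0_2 = n1 * (N + 1)  # doubled null mean of W

    dist = _ranksum_distribution(tuple(sorted(ranks2)), n1)
    sums = np.arange(dist.size)
    extreme = np.abs(sums - e0_2) >= abs(w_obs2 - e0_2) - 1e-9
    p = float(dist[extreme].sum() / dist.sum())
    return RankTestResult(W=w_obs2 / 2.0, n1=n1, n2=n2,
                          p_two_sided=min(p, 1.0), method="exact",
                          ties=_tie_profile(pooled))


def wilcoxon_approx(x, y) -> RankTestResult:
    """Normal-approximation rank-sum test with tie-corrected variance and
    continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    N = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    W = float(ranks[:n1].sum())
    E = n1 * (N + 1) / 2.0
    ties = _tie_profile(pooled)
    tie_term = sum(t**3 - t for t in ties) / (N * (N - 1)) if N > 1 else 0.0
    var = n1 * n2 / 12.0 * (N + 1 - tie_term)
    if var <= 0:
        return RankTestResult(W=W, n1=n1, n2=n2, p_two_sided=1.0,
                              method="normal_tie_corrected", ties=ties,
                              degenerate=True)
    z = (abs(W - E) - 0.5) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(max(z, 0.0))
    return RankTestResult(W=W, n1=n1, n2=n2, p_two_sided=float(min(p, 1.0)),
                          method="normal_tie_corrected", ties=ties)


def min_exact_p(n1: int, n2: int) -> float:
    """Smallest achievable two-sided exact p: 2 / C(n1+n2, n1) for the
    maximally separated (tie-free) configuration."""
    return 2.0 / math.comb(n1 + n2, n1)


# --------------------------------------------------------- null calibration

def null_calibration(n_tests: int = 100, n1: int = 15, n2: int = 15,
                     alpha: float = 0.05, replicates: int = 200,
                     seed: int = 0, method: str = "exact") -> dict:
    """Mean number of null tests reaching p < alpha.

    Simulates ``replicates`` batches of ``n_tests`` independent comparisons
    in which both groups are i.i.d. Uniform(0, 1) — any continuous law is
    equivalent under ranks — and averages the per-batch count of p < alpha.
    With 100 tests at alpha 0.05 the expectation is about five.
    """
    if min(n_tests, n1, n2, replicates) <= 0:
        raise ValueError("all sizes must be > 0")
    test = wilcoxon_exact if method == "exact" else wilcoxon_approx
    rng = np.random.default_rng(seed)
    counts = np.empty(replicates)
    for r in range(replicates):
        hits = 0
        data = rng.random((n_tests, n1 + n2))
        for row in data:
            if test(row[:n1], row[n1:]).p_two_sided < alpha:
                hits += 1
        counts[r] = hits
    return {
        "mean_significant": float(counts.mean()),
        "sd": float(counts.std(ddof=1)) if replicates > 1 else 0.0,
        "replicates": replicates,
        "n_tests": n_tests,
        "alpha": alpha,
        "counts": counts.tolist(),
    }


# ------------------------------------------------------------ multiplicity

@dataclass
class MultiplicityReport:
    m: int
    alpha: float
    expected_false_positives: float   # m * alpha, exactly
    observed_significant: int         # count with p < alpha
    verdicts: list[str]               # significant | ignored | not_significant
    q_values: list[float]             # Benjamini-Hochberg
    ignore_band_low: float


def multiplicity_report(p_values, alpha: float = 0.05,
                        ignore_band_low: float = 0.02) -> MultiplicityReport:
    """Expected-false-positive accounting plus BH q-values.

    The informal rule used for caste screens: with m tests, m * alpha false
    positives are expected, so p-values below alpha but above
    ``ignore_band_low`` are recorded as "ignored" (consistent with chance
    at this m) while only clearly smaller p-values count as significant.
    BH q-values are reported alongside as the principled alternative.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() <= 0 or p.max() > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    from statsmodels.stats.multitest import multipletests

    q = multipletests(p, method="fdr_bh")[1] if m else np.array([])
    verdicts = []
    for pi in p:
        if pi >= alpha:
            verdicts.append("not_significant")
        elif pi > ignore_band_low:
            verdicts.append("ignored")
        else:
            verdicts.append("significant")
    return MultiplicityReport(
        m=m, alpha=alpha, expected_false_positives=m * alpha,
        observed_significant=int((p < alpha).sum()), verdicts=verdicts,
        q_values=[float(v) for v in q], ignore_band_low=ignore_band_low,
    )
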