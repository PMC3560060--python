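"""Statistical kernels used throughout the pipeline.

Each test exposes an *exact* small-sample mode computed by full enumeration
(of rank splits or sign assignments), and a large-sample approximation with
tie and continuity corrections.  The exact modes double as self-contained
oracles: they depend on nothing but combinatorics, so the approximations and
the downstream analyses can be validated against them.

Directions are always stated for the first sample ``x``:
``greater`` means the alternative "x tends to be larger than y".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, sqrt
from typing import Sequence

import numpy as np
from scipy import special, stats as sps

EXACT_LIMIT = 12  # combined-sample cutoff for full enumeration


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    direction: str = "two_sided"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def chi_square_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Table layout: rows are groups, columns are outcomes::

        a  b
        c  d

    statistic = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), 1 df.
    A zero margin makes the statistic 0 and the p-value 1.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return TestResult(0.0, 1.0, "chi_square_2x2")
    stat = n * (a * d - b * c) ** 2 / denom
    return TestResult(float(stat), float(sps.chi2.sf(stat, df=1)), "chi_square_2x2")


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def rank_sum(
    x: Sequence[float], y: Sequence[float], direction: str = "two_sided"
) -> TestResult:
    """Wilcoxon rank-sum / Mann-Whitney U test.

    Exact p by enumerating all C(n+m, n) splits of the pooled midranks when
    the pooled sample has at most ``EXACT_LIMIT`` observations (with ties
    this is the exact permutation null over the observed midranks);
    otherwise a normal approximation with tie correction and a 0.5
    continuity correction.  The reported statistic is the Mann-Whitney U
    of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    if direction not in ("two_sided", "greater", "less"):
        raise ValueError(f"bad direction {direction!r}")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[:n].sum())
    u = w - n * (n + 1) / 2.0
    if np.ptp(pooled) == 0:
        return TestResult(u, 1.0, "rank_sum_exact", direction)

    if n + m <= EXACT_LIMIT:
        # enumerate every way to assign n of the pooled midranks to x
        total = comb(n + m, n)
        sums = np.fromiter(
            (sum(cm) for cm in itertools.combinations(ranks.tolist(), n)),
            dtype=float,
            count=total,
        )
        p_ge = float(np.count_nonzero(sums >= w)) / total
        p_le = float(np.count_nonzero(sums <= w)) / total
        p = _tail_p(p_ge, p_le, direction)
        return TestResult(u, p, "rank_sum_exact", direction)

    mu = n * m / 2.0
    tie_counts = np.unique(pooled, return_counts=True)[1]
    nt = n + m
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (nt * (nt - 1))
    var = n * m / 12.0 * (nt + 1 - tie_term)
    if var <= 0:
        return TestResult(u, 1.0, "rank_sum_normal", direction)
    sd = sqrt(var)
    # Edgeworth kurtosis term (exact null excess kurtosis of the untied
    # rank-sum) sharpens the tail near the exact-mode boundary; skipped
    # with ties, where the plain tie-corrected normal is used.
    g2 = 0.0
    if tie_counts.size == nt:
        g2 = -1.2 * (n * n + m * m + n * m + nt) / (n * m * (nt + 1))

    def _sf(z: float) -> float:
        return float(sps.norm.sf(z) + sps.norm.pdf(z) * (g2 / 24.0) * (z**3 - 3 * z))

    p_ge = min(1.0, max(0.0, _sf((u - mu - 0.5) / sd)))
    p_le = min(1.0, max(0.0, _sf(-(u - mu + 0.5) / sd)))
    return TestResult(u, _tail_p(p_ge, p_le, direction), "rank_sum_normal", direction)


def _tail_p(p_ge: float, p_le: float, direction: str) -> float:
    if direction == "greater":
        return min(1.0, p_ge)
    if direction == "less":
        return min(1.0, p_le)
    return min(1.0, 2.0 * min(p_ge, p_le))


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum over pooled values of the absolute ECDF difference;
    the p-value comes from the asymptotic Kolmogorov distribution.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / len(x)
    cdf_y = np.searchsorted(y, pooled, side="right") / len(y)
    d = float(np.abs(cdf_x - cdf_y).max())
    en = sqrt(len(x) * len(y) / (len(x) + len(y)))
    p = float(special.kolmogorov(en * d))
    return TestResult(d, min(1.0, p), "ks_two_sample")


def signed_rank(
    paired_x: Sequence[float], paired_y: Sequence[float], direction: str = "two_sided"
) -> TestResult:
    """Wilcoxon matched-pairs signed-rank test on ``x - y``.

    Zero differences are dropped.  Exact p by enumerating all 2^n sign
    assignments when n <= EXACT_LIMIT, else a normal approximation with
    tie and continuity corrections.  Statistic is W+, the rank sum of the
    positive differences.
    """
    x = np.asarray(paired_x, dtype=float)
    y = np.asarray(paired_y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    if len(x) < 1:
        raise ValueError("samples must be non-empty")
    if direction not in ("two_sided", "greater", "less"):
        raise ValueError(f"bad direction {direction!r}")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(0.0, 1.0, "signed_rank_exact", direction)
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_LIMIT:
        total = 2**n
        sums = np.zeros(1)
        for r in ranks:  # iterative convolution over sign choices
            sums = np.concatenate([sums, sums + r])
        p_ge = float(np.count_nonzero(sums >= w_plus)) / total
        p_le = float(np.count_nonzero(sums <= w_plus)) / total
        return TestResult(w_plus, _tail_p(p_ge, p_le, direction), "signed_rank_exact", direction)

    mu = n * (n + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float((tie_counts**3 - tie_counts).sum()) / 48.0
    if var <= 0:
        return TestResult(w_plus, 1.0, "signed_rank_normal", direction)
    sd = sqrt(var)
    p_ge = float(sps.norm.sf((w_plus - mu - 0.5) / sd))
    p_le = float(sps.norm.cdf((w_plus - mu + 0.5) / sd))
    return TestResult(w_plus, _tail_p(p_ge, p_le, direction), "signed_rank_normal", direction)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1; output order
    matches input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()
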