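"""Exact Wilcoxon-family tests and box-plot descriptors.

At the sample sizes of paired-recording experiments (a handful of cells),
asymptotic rank tests are inappropriate; both tests here enumerate the full
null distribution exactly for n ≤ 25 — the signed-rank test over all 2^n
sign assignments of the rank vector, the rank-sum test over all C(n1+n2, n1)
group assignments — with mid-ranks for tied magnitudes.  Beyond that size a
continuity-corrected normal approximation is used and flagged.

Conventions (documented, standard Wilcoxon practice): zero differences are
dropped before ranking; the one-tailed p for direction "greater" is
P(W+ ≥ w_obs) under the null; the two-tailed p is twice the smaller
one-tailed p, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["TestResult", "BoxStats", "signed_rank_exact", "rank_sum_exact", "box_stats"]

EXACT_N_MAX = 25


@dataclass
class TestResult:
    """Outcome of a rank test."""

    test: str
    statistic: float
    p_value: float
    sided: str
    direction: str | None
    n: int
    n2: int | None = None
    exact: bool = True
    degenerate: bool = False

    def __str__(self) -> str:  # p printed to two significant figures
        tail = self.sided if self.sided == "two" else f"one ({self.direction})"
        return (f"{self.test}: W={self.statistic:g}, p={float(f'{self.p_value:.2g}'):g} "
                f"({tail}-tailed, n={self.n}{'' if self.n2 is None else f',{self.n2}'}, "
                f"{'exact' if self.exact else 'approx'})")


@dataclass
class BoxStats:
    """Box-plot summary: quartiles plus Tukey whiskers at data points."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    mean: float


def _check_sided(sided: str, direction: str | None) -> None:
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    if sided == "one" and direction not in ("greater", "less"):
        raise ValueError("one-tailed test needs direction 'greater' or 'less'")


def signed_rank_exact(differences, sided: str = "two",
                      direction: str | None = None) -> TestResult:
    """Wilcoxon signed-rank test with an exactly enumerated null.

    ``differences`` are paired differences; zeros are dropped.  The
    statistic is W+ (sum of ranks of positive differences, mid-ranks for
    ties in magnitude).  For n ≤ 25 the null distribution of W+ over all
    2^n sign assignments is enumerated exactly (by subset-sum convolution,
    identical to brute-force enumeration); otherwise a continuity-corrected
    normal approximation is used and ``exact`` is False.
    """
    _check_sided(sided, direction)
    d = np.asarray(differences, dtype=np.float64)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult("signed_rank", 0.0, 1.0, sided, direction, 0, degenerate=True)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        # distribution over 2*W+ (integer since mid-ranks are multiples of 1/2)
        r2 = np.round(2 * ranks).astype(np.int64)
        counts = np.zeros(int(r2.sum()) + 1)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[:-r].copy()
        total = 2.0 ** n
        w2 = int(round(2 * w_plus))
        p_ge = counts[w2:].sum() / total
        p_le = counts[: w2 + 1].sum() / total
        exact = True
    else:
        mu = n * (n + 1) / 4.0
        # tie-corrected variance of W+
        var = (n * (n + 1) * (2 * n + 1)) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        sd = np.sqrt(var)
        p_ge = float(norm.sf((w_plus - 0.5 - mu) / sd))
        p_le = float(norm.cdf((w_plus + 0.5 - mu) / sd))
        exact = False
    if sided == "one":
        p = p_ge if direction == "greater" else p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return TestResult("signed_rank", w_plus, float(p), sided, direction, n, exact=exact)


def rank_sum_exact(x, y, sided: str = "two",
                   direction: str | None = None) -> TestResult:
    """Wilcoxon rank-sum (Mann–Whitney) test with an exactly enumerated null.

    The statistic is the rank sum of ``x`` within the pooled sample
    (mid-ranks for ties).  For n1 + n2 ≤ 25 the null distribution over all
    C(n1+n2, n1) assignments of ranks to the first group is enumerated
    exactly; otherwise a continuity-corrected normal approximation is used.
    ``direction='greater'`` means x tends larger than y.
    """
    _check_sided(sided, direction)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:n1].sum())
    nn = n1 + n2
    if nn <= EXACT_N_MAX:
        r2 = np.round(2 * ranks).astype(np.int64)
        smax = int(r2.sum())
        # counts[k, s] = number of k-subsets of the rank multiset with 2*sum == s
        counts = np.zeros((n1 + 1, smax + 1))
        counts[0, 0] = 1.0
        for r in r2:
            counts[1:, r:] += counts[:-1, :-r].copy()
        dist = counts[n1]
        total = dist.sum()  # == C(nn, n1)
        w2 = int(round(2 * w))
        p_ge = dist[w2:].sum() / total
        p_le = dist[: w2 + 1].sum() / total
        exact = True
    else:
        mu = n1 * (nn + 1) / 2.0
        var = n1 * n2 * (nn + 1) / 12.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= n1 * n2 * (tie_counts**3 - tie_counts).sum() / (12.0 * nn * (nn - 1))
        sd = np.sqrt(var)
        p_ge = float(norm.sf((w - 0.5 - mu) / sd))
        p_le = float(norm.cdf((w + 0.5 - mu) / sd))
        exact = False
    if sided == "one":
        p = p_ge if direction == "greater" else p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return TestResult("rank_sum", w, float(p), sided, direction, n1, n2, exact=exact)


def box_stats(values) -> BoxStats:
    """Median, quartiles (linear interpolation) and Tukey whiskers.

    Whiskers are the most extreme *data points* within 1.5×IQR of the
    quartiles, not the fence values themselves.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("box_stats needs at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxStats(
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        mean=float(v.mean()),
    )
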