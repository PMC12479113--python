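"""Rank-based and Welch statistics used by the audit.

`wilcoxon_rank_sum` follows the classical Mann-Whitney/Wilcoxon construction:
the Mann-Whitney U of the first sample with average ranks for ties; exact
tail probabilities by enumeration of rank assignments when the pooled sample
is small and tie-free, otherwise a normal approximation with tie correction
and continuity correction.  scipy's implementation is used only as an
independent cross-check in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class RankSumResult:
    statistic: float        # Mann-Whitney U of x
    p_value: float
    method: str             # "exact" or "normal"
    z: float | None = None


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided",
                      exact_limit: int = 12) -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney) test of two independent samples.

    Parameters
    ----------
    x, y : array-like
        Nonempty samples.
    alternative : {"two-sided", "less", "greater"}
        "less" tests the alternative that x is stochastically smaller than y.
    exact_limit : int
        Exact enumeration of all C(n+m, n) rank assignments is used when
        ``len(x) + len(y) <= exact_limit`` and there are no ties; otherwise
        the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u = float(ranks[:n].sum() - n * (n + 1) / 2.0)

    has_ties = np.unique(pooled).size < pooled.size
    if n + m <= exact_limit and not has_ties:
        # U over all equally likely assignments of n ranks out of n+m
        us = [sum(c) - n * (n + 1) / 2.0
              for c in combinations(range(1, n + m + 1), n)]
        total = len(us)
        le = sum(1 for v in us if v <= u) / total
        ge = sum(1 for v in us if v >= u) / total
        if alternative == "less":
            p = le
        elif alternative == "greater":
            p = ge
        else:
            p = min(1.0, 2.0 * min(le, ge))
        return RankSumResult(u, p, "exact")

    mean_u = n * m / 2.0
    nn = n + m
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((t_counts ** 3 - t_counts).sum()) / (nn * (nn - 1)))
    var_u = n * m / 12.0 * ((nn + 1) - tie_term)
    if var_u <= 0:
        return RankSumResult(u, 1.0, "normal", z=0.0)
    d = u - mean_u
    if alternative == "two-sided":
        z = (abs(d) - 0.5) / math.sqrt(var_u)
        z = max(z, 0.0)
        p = 2.0 * sps.norm.sf(z)
    elif alternative == "greater":
        z = (d - 0.5) / math.sqrt(var_u)
        p = sps.norm.sf(z)
    else:
        z = (d + 0.5) / math.sqrt(var_u)
        p = sps.norm.cdf(z)
    return RankSumResult(u, min(1.0, float(p)), "normal", z=float(z))


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_value: float
    degenerate: bool = False


def welch_t_test(x, y) -> WelchResult:
    """Welch's two-sample t-test (unequal variances), two-sided.

    Satterthwaite degrees of freedom.  When both samples have zero variance
    the statistic is undefined; the result is flagged degenerate with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 observations per sample")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        return WelchResult(math.nan, math.nan, 1.0, degenerate=True)
    se2 = vx / x.size + vy / y.size
    t = float((x.mean() - y.mean()) / math.sqrt(se2))
    df = se2 ** 2 / (vx ** 2 / (x.size ** 2 * (x.size - 1))
                     + vy ** 2 / (y.size ** 2 * (y.size - 1)))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return WelchResult(t, float(df), p)
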