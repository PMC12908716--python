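"""Exact small-sample nonparametric tests.

The study's quality checks rest on two classical tests applied at very small
n (a handful of recording segments, eight pointing targets): the Wilcoxon
signed-rank test and Spearman's rank correlation. At those sizes asymptotic
p-values are unreliable, so both tests are computed exactly — the signed-rank
null distribution by convolution over the (tie-averaged) ranks, which is
identical to enumerating all 2^n sign patterns, and the Spearman p by full
permutation enumeration — switching to the standard approximations only
beyond the exact-regime cutoffs.

Conventions
-----------
* Wilcoxon statistic = W+, the sum of ranks of the positive differences;
  zero differences are dropped, tied absolute differences get averaged ranks.
* Two-sided p = min(1, 2·min(P(W ≤ w), P(W ≥ w))) under the exact null.
* Spearman rho uses averaged ranks; the exact p is the fraction of the n!
  permutations of one margin with |rho| at least as extreme.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ParameterError

WILCOXON_EXACT_MAX_N = 25
SPEARMAN_EXACT_MAX_N = 9


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    n: int
    method: str


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of achievable 2·W+ values over all sign assignments.

    Subset-sum convolution: each rank is either in the positive set or not,
    so the generating polynomial is the product of (1 + x^r). Equivalent to
    enumerating the 2^n sign patterns, but polynomial time.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.concatenate([np.zeros(r), counts[: total + 1 - r]])
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(differences) -> TestResult:
    """Wilcoxon signed-rank test on a vector of paired differences.

    Exact two-sided p for n ≤ 25 non-zero differences, normal approximation
    (with tie correction) above.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ParameterError("differences must be a non-empty 1-D vector")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= WILCOXON_EXACT_MAX_N:
        doubled = np.rint(2.0 * ranks).astype(int)
        counts = _signed_rank_distribution(doubled)
        total = counts.sum()
        w2 = int(round(2.0 * w_plus))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        z = (w_plus - mu) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
        method = "normal-approx"
    return TestResult(statistic=w_plus, pvalue=float(p), n=n, method=method)


def spearman_correlation(x, y) -> TestResult:
    """Spearman rank correlation with exact permutation p for n ≤ 9.

    Raises if either margin is constant (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ParameterError("need at least 3 pairs")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("rank correlation undefined: constant margin")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    if n <= SPEARMAN_EXACT_MAX_N:
        perms = np.array(list(itertools.permutations(ry)))
        s = perms @ rx
        rho_all = (s / n - rx.mean() * ry.mean()) / (sx * sy)
        p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
        method = "exact"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        method = "t-approx"
    return TestResult(statistic=rho, pvalue=p, n=n, method=method)
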