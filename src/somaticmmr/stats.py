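"""Exact small-sample statistics used across the pipeline.

All hypergeometric quantities are computed with exact integer arithmetic
(``math.comb`` numerators over a shared denominator, converted to float once),
so p-values carry no accumulation error even deep in the tails.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats as _scipy_stats


def _hypergeom_numerators(N: int, K: int, n: int) -> tuple[int, list[int]]:
    """Support lower bound and integer pmf numerators over C(N, n) for Hypergeom(N, K, n)."""
    lo = max(0, n - (N - K))
    hi = min(K, n)
    nums = [math.comb(K, k) * math.comb(N - K, n - k) for k in range(lo, hi + 1)]
    return lo, nums


def hypergeom_sf_exact(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact."""
    lo, nums = _hypergeom_numerators(N, K, n)
    hi = lo + len(nums) - 1
    if k <= lo:
        return 1.0
    if k > hi:
        return 0.0
    tail = sum(nums[k - lo :])
    return float(Fraction(tail, math.comb(N, n)))


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Uses the point-probability (minimum-likelihood) convention: sum over all
    tables with the same margins whose probability does not exceed that of the
    observed table. Ties are resolved exactly thanks to integer numerators.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("table entries must be non-negative")
    N = a + b + c + d
    if N == 0:
        return 1.0
    K = a + c  # first-column total
    n = a + b  # first-row total
    lo, nums = _hypergeom_numerators(N, K, n)
    obs = nums[a - lo]
    total = sum(num for num in nums if num <= obs)
    return float(Fraction(total, math.comb(N, n)))


@dataclass
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p: float  # two-tailed
    method: str  # "exact" or "normal"


def _u_statistic(ranks: np.ndarray, idx_a, n_a: int) -> float:
    return float(ranks[list(idx_a)].sum() - n_a * (n_a + 1) / 2)


def mann_whitney_u(values_a, values_b, exact_limit: int = 12) -> MannWhitneyResult:
    """Two-tailed Mann-Whitney U test.

    Exact by full enumeration of rank splits when ``n_a + n_b <= exact_limit``
    (ties handled through midranks), otherwise the normal approximation with
    tie correction and a 0.5 continuity correction.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _scipy_stats.rankdata(pooled)
    u_obs = _u_statistic(ranks, range(n_a), n_a)
    mu = n_a * n_b / 2

    if np.ptp(pooled) == 0:
        return MannWhitneyResult(u=u_obs, p=1.0, method="degenerate")

    if n_a + n_b <= exact_limit:
        dev_obs = abs(u_obs - mu)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n_a + n_b), n_a):
            u = _u_statistic(ranks, idx, n_a)
            if abs(u - mu) >= dev_obs - 1e-9:
                count += 1
            total += 1
        return MannWhitneyResult(u=u_obs, p=count / total, method="exact")

    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var = n_a * n_b / 12 * ((n + 1) - tie_term)
    if var <= 0:
        return MannWhitneyResult(u=u_obs, p=1.0, method="degenerate")
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, 2 * _scipy_stats.norm.sf(z))
    return MannWhitneyResult(u=u_obs, p=p, method="normal")
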