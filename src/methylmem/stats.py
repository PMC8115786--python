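"""Shared statistical primitives.

The differentially-methylated-region scanner seeds on five-site windows, so the
rank-sum test backing it must be *exact* at very small sample sizes and must
tolerate ties (methylation levels are read-count fractions, which tie often).
The exact conditional distribution is computed over all C(n, nA) assignments of
the observed mid-ranks; ties are handled by mid-ranks, and the two-sided
p-value is the probability of a rank-sum at least as far from its conditional
mean as the observed one:

    p = P( |W' - E[W]| >= |W - E[W]| )

For equal group sizes the conditional distribution is symmetric, so this
coincides with the usual 2*min(tail) convention in the tie-free case.

All rank arithmetic is done on doubled ranks (mid-ranks are multiples of 1/2),
so tail comparisons are exact integer comparisons.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import norm, rankdata

# Route: full enumeration while C(n, nA) is small, exact dynamic programme up
# to _MAX_EXACT_N total observations, tie-corrected normal approximation above.
_MAX_ENUM = 20_000
_MAX_EXACT_N = 120


@lru_cache(maxsize=64)
def _comb_matrix(n: int, k: int) -> np.ndarray:
    """Boolean (C(n,k), n) matrix, one row per k-subset of range(n)."""
    m = np.zeros((comb(n, k), n), dtype=bool)
    for i, idx in enumerate(combinations(range(n), k)):
        m[i, list(idx)] = True
    return m


def _doubled_ranks(pooled: np.ndarray) -> np.ndarray:
    return np.rint(2.0 * rankdata(pooled)).astype(np.int64)


def _dp_rank_sum_distribution(ranks2: np.ndarray, n_a: int) -> np.ndarray:
    """Counts of k=n_a subsets by doubled-rank sum (0/1-knapsack DP)."""
    total = int(ranks2.sum())
    f = np.zeros((n_a + 1, total + 1))
    f[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(n_a, 0, -1):
            f[k, r:] += f[k - 1, : total + 1 - r]
    return f[n_a]


def exact_rank_sum_p(x, y) -> float:
    """Two-sided rank-sum test p-value of ``x`` vs ``y``.

    Exact (conditional on the observed mid-ranks) whenever the subset space is
    enumerable or the DP is affordable; tie-corrected normal approximation with
    continuity correction beyond ``_MAX_EXACT_N`` pooled observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_a, n_b = len(x), len(y)
    if n_a == 0 or n_b == 0:
        raise ValueError("both samples must be non-empty")
    n = n_a + n_b
    ranks2 = _doubled_ranks(np.concatenate([x, y]))
    w2 = int(ranks2[:n_a].sum())
    e2_num = n_a * (n + 1)  # doubled conditional mean of the rank sum
    d = abs(w2 - e2_num)
    if d == 0:
        return 1.0

    if comb(n, n_a) <= _MAX_ENUM:
        m = _comb_matrix(n, n_a)
        sums = m @ ranks2
        return float(np.mean(np.abs(sums - e2_num) >= d))

    if n <= _MAX_EXACT_N:
        dist = _dp_rank_sum_distribution(ranks2, n_a)
        s = np.arange(dist.size)
        tail = dist[np.abs(s - e2_num) >= d].sum()
        return float(tail / dist.sum())

    # tie-corrected normal approximation
    r = ranks2 / 2.0
    var = n_a * n_b / (n * (n - 1)) * (np.sum(r**2) - n * (n + 1) ** 2 / 4.0)
    if var <= 0:
        return 1.0
    z = (d / 2.0 - 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(z)))


def rank_sum_p_batch(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise exact rank-sum p-values for equal-width small windows.

    ``x`` and ``y`` are (m, k) arrays; row i is tested x[i] vs y[i]. Used by
    the DMR seeder, where k is the seed size (default 5) and full enumeration
    of C(2k, k) subsets is vectorised across all m windows at once.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, k = x.shape
    n = 2 * k
    if comb(n, k) > _MAX_ENUM:
        return np.array([exact_rank_sum_p(x[i], y[i]) for i in range(m)])
    pooled = np.concatenate([x, y], axis=1)
    ranks2 = np.rint(2.0 * rankdata(pooled, axis=1)).astype(np.int64)
    w2 = ranks2[:, :k].sum(axis=1)
    e2 = k * (n + 1)
    d = np.abs(w2 - e2)
    cm = _comb_matrix(n, k)
    sums = ranks2 @ cm.T  # (m, C(n,k))
    return np.mean(np.abs(sums - e2) >= d[:, None], axis=1)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (delegates to statsmodels)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
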