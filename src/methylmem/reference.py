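"""Naive reference implementations used to validate the production code.

These are deliberately plain — per-table integer enumeration for Fisher's
exact test, an explicit-loop seed-and-extend scan for DMRs, and a post-hoc
DMR validator — so the fast implementations in :mod:`methylmem.methylome`
can be checked against structurally independent code. They are part of the
package's validation surface, not alternatives for production use.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import rankdata

from .stats import exact_rank_sum_p
from .types import Dmr


def fisher_exact_oracle(meth_a: int, total_a: int, meth_b: int, total_b: int) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration.

    Integer weights, exact comparisons, one table at a time: sums P(k) over
    all outcomes k with P(k) <= P(observed) given the table margins.
    """
    n1, n2 = total_a, total_b
    m = meth_a + meth_b
    lo, hi = max(0, m - n2), min(n1, m)
    weights = {k: comb(n1, k) * comb(n2, m - k) for k in range(lo, hi + 1)}
    obs = weights[meth_a]
    total = sum(weights.values())
    return min(1.0, sum(w for w in weights.values() if w <= obs) / total)


def rank_sum_p_reference(x, y, enum_limit: int = 20_000) -> float:
    """Exact two-sided rank-sum p by literal subset enumeration.

    Falls back to the package's DP-based exact test when the subset space is
    too large to enumerate one combination at a time.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_a = len(x)
    pooled = np.concatenate([x, y])
    n = pooled.size
    if comb(n, n_a) > enum_limit:
        return exact_rank_sum_p(x, y)
    r2 = np.rint(2.0 * rankdata(pooled)).astype(int)
    w_obs = int(r2[:n_a].sum())
    e2 = n_a * (n + 1)
    d = abs(w_obs - e2)
    if d == 0:
        return 1.0
    hits = tot = 0
    for idx in combinations(range(n), n_a):
        s = sum(int(r2[i]) for i in idx)
        tot += 1
        if abs(s - e2) >= d:
            hits += 1
    return hits / tot


def brute_force_dmrs(
    pos,
    level_a,
    level_b,
    contig: str = "ctg1",
    context: str = "CG",
    seed_size: int = 5,
    min_trend: int = 4,
    alpha: float = 0.05,
    max_gap: int = 200,
) -> list[Dmr]:
    """Explicit-loop seed-and-extend reference scan over one contig.

    Enumerates every candidate seed window and extension path with plain
    Python loops, re-deriving the gap rule, the trend rule and the rank-sum
    test at each step.
    """
    pos = [int(p) for p in pos]
    la = [float(v) for v in level_a]
    lb = [float(v) for v in level_b]
    n = len(pos)
    out: list[Dmr] = []
    i = 0
    while i + seed_size <= n:
        window = list(range(i, i + seed_size))
        ok_gaps = all(
            pos[b] - pos[a] <= max_gap for a, b in zip(window, window[1:])
        )
        if not ok_gaps:
            i += 1
            continue
        ups = sum(1 for j in window if lb[j] > la[j])
        downs = sum(1 for j in window if lb[j] < la[j])
        if ups >= min_trend and ups > downs:
            trend = 1
        elif downs >= min_trend and downs > ups:
            trend = -1
        else:
            i += 1
            continue
        p = rank_sum_p_reference([la[j] for j in window], [lb[j] for j in window])
        if not p < alpha:
            i += 1
            continue
        members = list(window)
        p_final = p
        j = i + seed_size
        while j < n:
            if pos[j] - pos[members[-1]] > max_gap:
                break
            d = lb[j] - la[j]
            if (trend == 1 and not d > 0) or (trend == -1 and not d < 0):
                break
            trial = members + [j]
            p_trial = rank_sum_p_reference(
                [la[t] for t in trial], [lb[t] for t in trial]
            )
            if not p_trial < alpha:
                break
            members = trial
            p_final = p_trial
            j += 1
        mean_a = sum(la[t] for t in members) / len(members)
        mean_b = sum(lb[t] for t in members) / len(members)
        out.append(
            Dmr(
                contig=contig,
                start=pos[members[0]],
                end=pos[members[-1]],
                context=context,
                positions=tuple(pos[t] for t in members),
                direction="hyper" if mean_b > mean_a else "hypo",
                p_value=p_final,
                mean_level_num=mean_b,
                mean_level_den=mean_a,
            )
        )
        i = members[-1] + 1
    return out


def validate_dmr(
    dmr: Dmr,
    pos,
    level_a,
    level_b,
    seed_size: int = 5,
    min_trend: int = 4,
    alpha: float = 0.05,
    max_gap: int = 200,
) -> list[str]:
    """Independent post-hoc check of one called DMR's invariants.

    Returns a list of violation messages (empty = valid): membership count,
    consecutive-gap rule, trend-sign count, direction consistency and the
    final rank-sum p re-computed from the member levels.
    """
    problems = []
    index = {int(p): k for k, p in enumerate(pos)}
    members = [index.get(p) for p in dmr.positions]
    if any(m is None for m in members):
        return ["member position not present in the site table"]
    if len(members) < seed_size:
        problems.append(f"only {len(members)} member sites (< {seed_size})")
    for a, b in zip(dmr.positions, dmr.positions[1:]):
        if b - a > max_gap:
            problems.append(f"gap {b - a} bp between {a} and {b} exceeds {max_gap}")
        if b <= a:
            problems.append("member positions not strictly increasing")
    la = [float(level_a[m]) for m in members]
    lb = [float(level_b[m]) for m in members]
    sign = 1 if dmr.direction == "hyper" else -1
    n_trend = sum(1 for a, b in zip(la, lb) if (b - a) * sign > 0)
    if n_trend < min_trend:
        problems.append(f"only {n_trend} members share the {dmr.direction} trend")
    mean_delta = sum(b - a for a, b in zip(la, lb)) / len(la)
    if mean_delta * sign <= 0:
        problems.append("direction inconsistent with mean level difference")
    p = exact_rank_sum_p(la, lb)
    if not p < alpha:
        problems.append(f"final rank-sum p {p} not < {alpha}")
    if abs(p - dmr.p_value) > 1e-9:
        problems.append(f"stored p {dmr.p_value} != recomputed {p}")
    return problems
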