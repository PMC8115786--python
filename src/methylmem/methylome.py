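"""Methylome statistics: site levels, mC calls, DMCs, DMRs, region means.

The DMC test is Fisher's exact test (two-sided, minimum-likelihood
convention) on the [[meth_A, unmeth_A], [meth_B, unmeth_B]] table, with a
differentially-methylated call requiring |level_B - level_A| >= 0.20 as well
as p < alpha. The batch implementation computes the hypergeometric weights
as exact integers per unique table margin, so p-values carry no more than
float-division rounding.

The DMR caller is a seed-and-extend scan: a seed is a window of five
adjacent same-context sites (consecutive inter-distances <= 200 bp) with at
least four sites changing in the same direction and an exact two-sided
Wilcoxon rank-sum p < alpha on the window's paired site levels; seeds extend
3' one site at a time while the trend, the gap rule and the re-run test all
hold, and scanning resumes past each emitted region.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import binom

from .stats import exact_rank_sum_p, rank_sum_p_batch
from .types import CONTEXTS, Dmr


# ---------------------------------------------------------------------------
# site-level primitives


def site_level(meth_count: int, total_count: int) -> float:
    """Methylation level = methylated reads / total reads at one site."""
    if total_count <= 0:
        raise ValueError("total_count must be >= 1")
    return meth_count / total_count


def call_mc_site(
    meth_count: int,
    total_count: int,
    error_rate: float = 0.005,
    alpha: float = 0.05,
) -> bool:
    """Is this site methylated above the bisulfite non-conversion error?

    One-sided binomial test of ``meth_count`` successes in ``total_count``
    trials against ``error_rate``; methylated iff the upper-tail p < alpha.
    """
    p = binom.sf(meth_count - 1, total_count, error_rate)
    return bool(p < alpha)


def call_mc_sites(
    meth: np.ndarray, total: np.ndarray, error_rate: float = 0.005, alpha: float = 0.05
) -> np.ndarray:
    """Vectorised :func:`call_mc_site`."""
    return binom.sf(np.asarray(meth) - 1, np.asarray(total), error_rate) < alpha


def global_summary(
    sites: pd.DataFrame,
    min_coverage: int = 4,
    error_rate: float = 0.005,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-context mC frequency and mean methylation level for one sample.

    Frequency is the percentage of covered cytosines called methylated; the
    headline mean level is computed over called-mC sites (the convention
    behind per-context "average methylation level" figures), with the
    all-site mean also reported.
    """
    df = sites[sites["total_count"] >= min_coverage]
    rows = []
    for ctx in CONTEXTS:
        sub = df[df["context"] == ctx]
        n = len(sub)
        if n == 0:
            rows.append(
                {
                    "context": ctx, "n_covered": 0, "n_mc": 0,
                    "mc_frequency_pct": np.nan, "mean_level_mc_pct": np.nan,
                    "mean_level_all_pct": np.nan,
                }
            )
            continue
        levels = sub["meth_count"].to_numpy() / sub["total_count"].to_numpy()
        is_mc = call_mc_sites(
            sub["meth_count"].to_numpy(), sub["total_count"].to_numpy(),
            error_rate, alpha,
        )
        n_mc = int(is_mc.sum())
        rows.append(
            {
                "context": ctx,
                "n_covered": n,
                "n_mc": n_mc,
                "mc_frequency_pct": 100.0 * n_mc / n,
                "mean_level_mc_pct": 100.0 * levels[is_mc].mean() if n_mc else np.nan,
                "mean_level_all_pct": 100.0 * levels.mean(),
            }
        )
    return pd.DataFrame(rows).set_index("context")


# ---------------------------------------------------------------------------
# site pairing


def pair_sites(
    sites_den: pd.DataFrame, sites_num: pd.DataFrame, min_coverage: int = 4
) -> pd.DataFrame:
    """Join two samples' site tables on (contig, position, strand, context).

    The first argument is the contrast's denominator sample (A), the second
    the numerator (B); ``delta`` = level_B - level_A. Sites must reach
    ``min_coverage`` in both samples.
    """
    key = ["contig", "position", "strand", "context"]
    a = sites_den[sites_den["total_count"] >= min_coverage]
    b = sites_num[sites_num["total_count"] >= min_coverage]
    merged = a.merge(b, on=key, suffixes=("_a", "_b"), how="inner")
    merged["level_a"] = merged["meth_count_a"] / merged["total_count_a"]
    merged["level_b"] = merged["meth_count_b"] / merged["total_count_b"]
    merged["delta"] = merged["level_b"] - merged["level_a"]
    return merged.sort_values(["contig", "position"], kind="stable").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# DMC calling


@lru_cache(maxsize=500_000)
def _margin_weights(n1: int, n2: int, m: int):
    """Exact integer hypergeometric weights for one table margin.

    Returns (lo, weights, sorted_weights, cumulative, total) where weights[k-lo]
    = C(n1,k)*C(n2,m-k) over the support, sorted_weights is ascending, and
    cumulative holds float partial sums of sorted_weights.
    """
    lo = max(0, m - n2)
    hi = min(n1, m)
    weights = tuple(comb(n1, k) * comb(n2, m - k) for k in range(lo, hi + 1))
    sorted_w = tuple(sorted(weights))
    cum = np.cumsum(np.array(sorted_w, dtype=float))
    return lo, weights, sorted_w, cum, float(sum(weights))


def _fisher_two_sided_batch(
    ma: np.ndarray, ta: np.ndarray, mb: np.ndarray, tb: np.ndarray
) -> np.ndarray:
    """Two-sided Fisher p for tables [[ma, ta-ma], [mb, tb-mb]].

    Minimum-likelihood convention: sums the probabilities of all outcomes no
    more likely than the observed one. Hypergeometric weights are exact
    integers (compared exactly, no epsilon), computed once per unique margin
    and cached across calls; identical tables are deduplicated up front.
    """
    ma = np.asarray(ma, dtype=np.int64)
    ta = np.asarray(ta, dtype=np.int64)
    mb = np.asarray(mb, dtype=np.int64)
    tb = np.asarray(tb, dtype=np.int64)
    key = ((ta.astype(np.int64) * 4096 + tb) * 4096 + ma) * 4096 + mb
    uniq, inverse = np.unique(key, return_inverse=True)
    p_uniq = np.empty(uniq.size)
    for i, k in enumerate(uniq):
        k = int(k)
        b = k % 4096
        k //= 4096
        a = k % 4096
        k //= 4096
        n2 = k % 4096
        n1 = k // 4096
        lo, weights, sorted_w, cum, total = _margin_weights(n1, n2, a + b)
        pos = bisect.bisect_right(sorted_w, weights[a - lo])
        p_uniq[i] = cum[pos - 1] / total
    return np.minimum(p_uniq[inverse], 1.0)


def call_dmc(
    meth_a: int,
    total_a: int,
    meth_b: int,
    total_b: int,
    min_delta: float = 0.20,
    alpha: float = 0.05,
) -> tuple[bool, float, str]:
    """DMC decision for one site pair: (is_dmc, p_value, direction).

    Direction ("hyper"/"hypo") is w.r.t. the numerator sample B; a DMC needs
    both p < alpha and an absolute level change >= ``min_delta``.
    """
    p = float(
        _fisher_two_sided_batch(
            np.array([meth_a]), np.array([total_a]),
            np.array([meth_b]), np.array([total_b]),
        )[0]
    )
    delta = meth_b / total_b - meth_a / total_a
    is_dmc = p < alpha and abs(delta) >= min_delta
    return is_dmc, p, "hyper" if delta > 0 else "hypo"


def call_dmcs(
    pairs: pd.DataFrame, min_delta: float = 0.20, alpha: float = 0.05
) -> pd.DataFrame:
    """Vectorised DMC calling over a paired site table.

    Adds columns ``p_value``, ``is_dmc`` and ``direction`` to a copy of
    ``pairs``.
    """
    out = pairs.copy()
    out["p_value"] = _fisher_two_sided_batch(
        pairs["meth_count_a"].to_numpy(), pairs["total_count_a"].to_numpy(),
        pairs["meth_count_b"].to_numpy(), pairs["total_count_b"].to_numpy(),
    )
    out["is_dmc"] = (out["p_value"] < alpha) & (out["delta"].abs() >= min_delta)
    out["direction"] = np.where(out["delta"] > 0, "hyper", "hypo")
    return out


# ---------------------------------------------------------------------------
# DMR calling


@dataclass(frozen=True)
class DmrParams:
    seed_size: int = 5
    min_trend: int = 4
    alpha: float = 0.05
    max_gap: int = 200


def call_dmrs(
    pairs: pd.DataFrame,
    context: str,
    seed_size: int = 5,
    min_trend: int = 4,
    alpha: float = 0.05,
    max_gap: int = 200,
) -> list[Dmr]:
    """Seed-and-extend DMR scan over one context of a paired site table.

    See the module docstring for the algorithm; sites with delta == 0 count
    toward neither trend and terminate extension.
    """
    dmrs: list[Dmr] = []
    sub = pairs[pairs["context"] == context]
    for contig, grp in sub.groupby("contig", sort=True):
        grp = grp.sort_values("position", kind="stable")
        dmrs.extend(
            _scan_contig(
                str(contig),
                grp["position"].to_numpy(),
                grp["level_a"].to_numpy(),
                grp["level_b"].to_numpy(),
                context, seed_size, min_trend, alpha, max_gap,
            )
        )
    return dmrs


def _scan_contig(
    contig: str,
    pos: np.ndarray,
    la: np.ndarray,
    lb: np.ndarray,
    context: str,
    seed_size: int,
    min_trend: int,
    alpha: float,
    max_gap: int,
) -> list[Dmr]:
    n = pos.size
    if n < seed_size:
        return []
    delta = lb - la
    sign = np.sign(delta).astype(np.int8)

    # window precomputation: gap admissibility and trend counts
    k = seed_size
    gap_ok_step = np.diff(pos) <= max_gap  # between consecutive sites
    win_gap_ok = np.all(
        np.lib.stride_tricks.sliding_window_view(gap_ok_step, k - 1), axis=1
    )
    pos_cnt = np.convolve((sign > 0).astype(int), np.ones(k, dtype=int), "valid")
    neg_cnt = np.convolve((sign < 0).astype(int), np.ones(k, dtype=int), "valid")
    cand_sign = np.zeros(n - k + 1, dtype=np.int8)
    cand_sign[(pos_cnt >= min_trend) & (pos_cnt > neg_cnt)] = 1
    cand_sign[(neg_cnt >= min_trend) & (neg_cnt > pos_cnt)] = -1
    candidate = win_gap_ok & (cand_sign != 0)

    # batch the exact rank-sum test over all candidate seed windows
    p_seed = np.full(n - k + 1, np.nan)
    idx = np.flatnonzero(candidate)
    if idx.size:
        wa = np.lib.stride_tricks.sliding_window_view(la, k)[idx]
        wb = np.lib.stride_tricks.sliding_window_view(lb, k)[idx]
        p_seed[idx] = rank_sum_p_batch(wa, wb)

    dmrs: list[Dmr] = []
    i = 0
    while i <= n - k:
        if not candidate[i] or not p_seed[i] < alpha:
            i += 1
            continue
        s = int(cand_sign[i])
        members = list(range(i, i + k))
        p_final = float(p_seed[i])
        j = i + k
        while j < n:
            if pos[j] - pos[members[-1]] > max_gap or sign[j] != s:
                break
            ext = members + [j]
            p_ext = exact_rank_sum_p(la[ext], lb[ext])
            if not p_ext < alpha:
                break
            members = ext
            p_final = float(p_ext)
            j += 1
        mean_a = float(la[members].mean())
        mean_b = float(lb[members].mean())
        dmrs.append(
            Dmr(
                contig=contig,
                start=int(pos[members[0]]),
                end=int(pos[members[-1]]),
                context=context,
                positions=tuple(int(p) for p in pos[members]),
                direction="hyper" if mean_b > mean_a else "hypo",
                p_value=p_final,
                mean_level_num=mean_b,
                mean_level_den=mean_a,
            )
        )
        i = members[-1] + 1
    return dmrs


# ---------------------------------------------------------------------------
# region aggregation


def region_methylation(
    sites: pd.DataFrame,
    contig: str,
    interval: tuple[int, int] | None,
    context: str,
    min_sites: int = 3,
) -> tuple[float, int]:
    """Unweighted mean site level of one context inside one interval.

    Returns (mean_level, n_sites); the mean is NaN when fewer than
    ``min_sites`` covered sites fall in the interval.
    """
    if interval is None:
        return np.nan, 0
    sub = sites[
        (sites["contig"] == contig)
        & (sites["context"] == context)
        & (sites["position"] >= interval[0])
        & (sites["position"] <= interval[1])
    ]
    n = len(sub)
    if n < min_sites:
        return np.nan, n
    levels = sub["meth_count"].to_numpy() / sub["total_count"].to_numpy()
    return float(levels.mean()), n


def region_levels_for_genes(
    sites: pd.DataFrame,
    genes: list,
    region: str = "promoter",
    context: str = "CG",
    flank_bp: int = 2000,
    min_sites: int = 3,
    min_coverage: int = 4,
) -> pd.Series:
    """Per-gene mean methylation level of one region type (vectorised).

    ``region`` is "promoter", "body" or "downstream"; genes whose region has
    fewer than ``min_sites`` covered context sites get NaN.
    """
    from .types import derive_regions

    df = sites[
        (sites["context"] == context) & (sites["total_count"] >= min_coverage)
    ]
    by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig, grp in df.groupby("contig", sort=False):
        grp = grp.sort_values("position", kind="stable")
        levels = grp["meth_count"].to_numpy() / grp["total_count"].to_numpy()
        by_contig[str(contig)] = (grp["position"].to_numpy(), np.concatenate([[0.0], np.cumsum(levels)]))

    out = {}
    for g in genes:
        interval = derive_regions(g, flank_bp)[region]
        if interval is None or g.contig not in by_contig:
            out[g.gene_id] = np.nan
            continue
        posarr, cumsum = by_contig[g.contig]
        lo = np.searchsorted(posarr, interval[0], side="left")
        hi = np.searchsorted(posarr, interval[1], side="right")
        n = hi - lo
        out[g.gene_id] = (cumsum[hi] - cumsum[lo]) / n if n >= min_sites else np.nan
    return pd.Series(out, name=f"{region}_{context}_level")


# ---------------------------------------------------------------------------
# metagene profiles


def metagene_profile(
    sites: pd.DataFrame,
    genes: list,
    expression_class: pd.Series,
    n_bins: int = 20,
    flank_bp: int = 2000,
    min_coverage: int = 4,
) -> pd.DataFrame:
    """Binned mean methylation around genes, stratified by expression class.

    Flanks use fixed-width bins (flank_bp / n_bins); gene bodies are
    length-normalised into ``n_bins`` bins with exonic and intronic cytosines
    tracked as separate segments. Orientation is 5'->3' (bin 0 of the
    upstream segment is farthest from the TSS). Site levels are pooled across
    all genes of a class before averaging.

    Returns a tidy frame: context, expr_class, segment, bin, mean_level,
    n_sites.
    """
    df = sites[sites["total_count"] >= min_coverage]
    by_contig = {
        str(c): g.sort_values("position", kind="stable")
        for c, g in df.groupby("contig", sort=False)
    }
    acc: dict[tuple, tuple[float, int]] = {}

    def _add(ctx, cls, segment, bins, levels):
        for b, lv in zip(bins, levels):
            key = (ctx, cls, segment, int(b))
            s, c = acc.get(key, (0.0, 0))
            acc[key] = (s + lv, c + 1)

    for g in genes:
        cls = expression_class.get(g.gene_id)
        if cls is None or (isinstance(cls, float) and np.isnan(cls)):
            continue
        sub_all = by_contig.get(g.contig)
        if sub_all is None:
            continue
        from .types import derive_regions

        # derive_regions is already strand-aware: "promoter" is the 5' flank
        regions = derive_regions(g, flank_bp)
        up_iv = regions["promoter"]
        dn_iv = regions["downstream"]

        posarr = sub_all["position"].to_numpy()
        lv = sub_all["meth_count"].to_numpy() / sub_all["total_count"].to_numpy()
        ctxarr = sub_all["context"].to_numpy()

        def _slice(iv):
            lo = np.searchsorted(posarr, iv[0], side="left")
            hi = np.searchsorted(posarr, iv[1], side="right")
            return slice(lo, hi)

        glen = g.end - g.start + 1
        for ctx in CONTEXTS:
            # upstream flank (5' of the TSS)
            if up_iv is not None:
                sl = _slice(up_iv)
                m = ctxarr[sl] == ctx
                p = posarr[sl][m]
                width = up_iv[1] - up_iv[0] + 1
                rel = (p - up_iv[0]) if g.strand == "+" else (up_iv[1] - p)
                b = np.minimum((rel / width * n_bins).astype(int), n_bins - 1)
                _add(ctx, cls, "upstream", b, lv[sl][m])
            # body, split into exon / intron
            sl = _slice((g.start, g.end))
            m = ctxarr[sl] == ctx
            p = posarr[sl][m]
            rel = (p - g.start) if g.strand == "+" else (g.end - p)
            b = np.minimum((rel / glen * n_bins).astype(int), n_bins - 1)
            in_exon = np.zeros(p.size, dtype=bool)
            for es, ee in g.exons:
                in_exon |= (p >= es) & (p <= ee)
            _add(ctx, cls, "exon", b[in_exon], lv[sl][m][in_exon])
            _add(ctx, cls, "intron", b[~in_exon], lv[sl][m][~in_exon])
            # downstream flank (3' of the gene end)
            if dn_iv is not None:
                sl = _slice(dn_iv)
                m = ctxarr[sl] == ctx
                p = posarr[sl][m]
                width = dn_iv[1] - dn_iv[0] + 1
                rel = (p - dn_iv[0]) if g.strand == "+" else (dn_iv[1] - p)
                b = np.minimum((rel / width * n_bins).astype(int), n_bins - 1)
                _add(ctx, cls, "downstream", b, lv[sl][m])

    rows = [
        {
            "context": k[0], "expr_class": k[1], "segment": k[2], "bin": k[3],
            "mean_level": s / c, "n_sites": c,
        }
        for k, (s, c) in sorted(acc.items())
    ]
    return pd.DataFrame(rows)
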