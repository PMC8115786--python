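"""Coupling the methylome to the transcriptome.

Promoter-methylation quartile classes, expression-by-class rank tests,
expression/methylation correlations, the methylation-regulated-gene (MRG)
screen and its intersection with the stress-memory categories.

An MRG is a DEG whose promoter methylation moved the opposite way in the
same contrast, in a symmetric cytosine context (CG or CHG — contexts with a
methylated cytosine on both strands, which maintenance methyltransferases
propagate through replication): up-regulated with a promoter hypo-DMR, or
down-regulated with a promoter hyper-DMR.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .stats import exact_rank_sum_p
from .types import Dmr, GeneModel, MrgCall, derive_regions


# ---------------------------------------------------------------------------
# promoter quartile classes


def classify_promoters(levels: pd.Series) -> pd.Series:
    """Quartile classes of per-gene promoter methylation levels.

    "methylated" strictly above the upper quartile, "unmethylated" strictly
    below the lower quartile, "intermediate" otherwise (ties at a quartile
    included), "missing" where the level is NaN. Quartiles use linear
    interpolation over the non-missing genes; fewer than 8 genes with data is
    an error.
    """
    data = levels.dropna()
    if len(data) < 8:
        raise ValueError("quartile classification needs >= 8 genes with data")
    q1, q3 = np.quantile(data.to_numpy(), [0.25, 0.75])
    out = pd.Series("missing", index=levels.index, name="promoter_class")
    out[data.index[data > q3]] = "methylated"
    out[data.index[data < q1]] = "unmethylated"
    out[data.index[(data >= q1) & (data <= q3)]] = "intermediate"
    return out


def expression_by_promoter_class(
    fpkm: pd.Series, classes: pd.Series, exact_limit: int = 50
) -> dict:
    """Rank-sum test of expression between promoter-methylated and
    -unmethylated genes.

    Two-sided Wilcoxon rank-sum on the FPKM values (ranks are invariant to
    the log scale used for display); exact conditional test when the pooled
    size is small, tie-corrected normal approximation above ``exact_limit``.
    Returns p, group medians and sizes; missing (p = NaN) if a class is
    empty.
    """
    meth = fpkm[classes[classes == "methylated"].index].dropna()
    unmeth = fpkm[classes[classes == "unmethylated"].index].dropna()
    if len(meth) == 0 or len(unmeth) == 0:
        return {
            "p_value": np.nan, "n_methylated": len(meth),
            "n_unmethylated": len(unmeth),
            "median_methylated": np.nan, "median_unmethylated": np.nan,
        }
    p = exact_rank_sum_p(meth.to_numpy(), unmeth.to_numpy())
    return {
        "p_value": p,
        "n_methylated": len(meth),
        "n_unmethylated": len(unmeth),
        "median_methylated": float(meth.median()),
        "median_unmethylated": float(unmeth.median()),
    }


# ---------------------------------------------------------------------------
# correlations


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    n = x.size
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan, n
    r, p = pearsonr(x, y)
    if n == 3 and abs(r) >= 1.0 - 1e-12:
        warnings.warn(
            "perfect correlation at n=3: p-value is the degenerate analytic "
            "limit; insufficient n for inference",
            stacklevel=3,
        )
    return float(r), float(p), n


def correlate_fc_vs_promoter_delta(
    de: pd.DataFrame, promoter_delta: pd.Series
) -> dict[str, dict]:
    """Pearson correlation of log2 fold change vs promoter level change.

    Returns results for all genes with both quantities and for the DEG-only
    subset (|FC| >= 2 and adjusted p <= 0.05 flags as carried in ``de``).
    """
    joined = de.join(promoter_delta.rename("delta"), how="inner").dropna(
        subset=["log2_fc", "delta"]
    )
    out = {}
    for which, sub in (
        ("all_genes", joined),
        ("deg_only", joined[joined["deg_flag"] != "none"]),
    ):
        r, p, n = _pearson(
            sub["log2_fc"].to_numpy(dtype=float), sub["delta"].to_numpy(dtype=float)
        )
        out[which] = {"r": r, "p_value": p, "n": n}
    return out


def correlate_pathway_genes(
    metrics: pd.DataFrame, expression: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Correlate per-sample methylation metrics with pathway-gene expression.

    ``metrics``: samples x metric columns (e.g. mC frequency / mean level per
    context); ``expression``: samples x gene columns (e.g. FPKM of the
    methylation-pathway genes). Every (gene, metric) pair is tested; pairs
    significant at p <= alpha are flagged.
    """
    shared = metrics.index.intersection(expression.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    rows = []
    for gene in expression.columns:
        for metric in metrics.columns:
            r, p, n = _pearson(
                expression.loc[shared, gene].to_numpy(dtype=float),
                metrics.loc[shared, metric].to_numpy(dtype=float),
            )
            rows.append(
                {
                    "gene": gene, "metric": metric, "r": r, "p_value": p,
                    "n": n, "significant": bool(p <= alpha) if np.isfinite(p) else False,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MRG screen


SYMMETRIC_CONTEXTS = ("CG", "CHG")


def screen_mrgs(
    de: pd.DataFrame,
    dmrs: list[Dmr],
    genes: list[GeneModel],
    contrast: str,
    flank_bp: int = 2000,
    contexts: tuple[str, ...] = SYMMETRIC_CONTEXTS,
) -> list[MrgCall]:
    """Screen one contrast's DEGs for opposite-direction promoter DMRs.

    A gene is an MRG iff it is an up-DEG with >= 1 bp of promoter overlap by
    a hypo-DMR, or a down-DEG overlapped by a hyper-DMR, in a symmetric
    context. Promoters are strand-aware 2-kb upstream flanks.
    """
    dmrs = [d for d in dmrs if d.context in contexts]
    by_contig: dict[str, list[Dmr]] = {}
    for d in dmrs:
        by_contig.setdefault(d.contig, []).append(d)

    calls: list[MrgCall] = []
    for g in genes:
        if g.gene_id not in de.index:
            continue
        flag = de.loc[g.gene_id, "deg_flag"]
        promoter = derive_regions(g, flank_bp)["promoter"]
        support: list[Dmr] = []
        if flag in ("up", "down") and promoter is not None:
            want = "hypo" if flag == "up" else "hyper"
            for d in by_contig.get(g.contig, []):
                if d.direction == want and d.start <= promoter[1] and d.end >= promoter[0]:
                    support.append(d)
        calls.append(
            MrgCall(
                gene_id=g.gene_id,
                contrast=contrast,
                de_direction=str(flag),
                supporting_dmrs=tuple(support),
                is_mrg=bool(support),
            )
        )
    return calls


def screen_mrgs_by_dmc(
    de: pd.DataFrame,
    dmcs: pd.DataFrame,
    genes: list[GeneModel],
    contrast: str,
    flank_bp: int = 2000,
    contexts: tuple[str, ...] = SYMMETRIC_CONTEXTS,
    min_dmcs: int = 2,
) -> list[MrgCall]:
    """Alternative MRG criterion: >= ``min_dmcs`` promoter DMCs of the
    required sign (instead of a called DMR). ``dmcs`` is the output of
    :func:`methylmem.methylome.call_dmcs`.
    """
    sig = dmcs[dmcs["is_dmc"] & dmcs["context"].isin(contexts)]
    calls: list[MrgCall] = []
    for g in genes:
        if g.gene_id not in de.index:
            continue
        flag = de.loc[g.gene_id, "deg_flag"]
        promoter = derive_regions(g, flank_bp)["promoter"]
        n_support = 0
        if flag in ("up", "down") and promoter is not None:
            want = "hypo" if flag == "up" else "hyper"
            sub = sig[
                (sig["contig"] == g.contig)
                & (sig["position"] >= promoter[0])
                & (sig["position"] <= promoter[1])
                & (sig["direction"] == want)
            ]
            n_support = len(sub)
        calls.append(
            MrgCall(
                gene_id=g.gene_id, contrast=contrast, de_direction=str(flag),
                supporting_dmrs=(), is_mrg=n_support >= min_dmcs,
            )
        )
    return calls


def mrg_sets(calls: list[MrgCall]) -> set:
    return {c.gene_id for c in calls if c.is_mrg}


ACCLIMATION_CONTRASTS = ("SD/F", "A/SD")
DEHYDRATION_CONTRASTS = ("FD/F", "AD/A", "F4D/F4", "A4D/A4", "F18D/F18", "A18D/A18")


def intersect_memory_mrgs(
    memory_sets: dict[str, dict[str, set]],
    mrg_by_contrast: dict[str, list[MrgCall]],
    categories: tuple[str, ...] = ("short", "mid"),
    acclimation_contrasts: tuple[str, ...] = ACCLIMATION_CONTRASTS,
    dehydration_contrasts: tuple[str, ...] = DEHYDRATION_CONTRASTS,
) -> dict[str, dict[str, set]]:
    """Memory genes that are also methylation-regulated.

    For each memory category, intersects the (up + down) memory gene set with
    the union of MRG sets from the acclimation-related contrasts, from the
    rapid-dehydration contrasts, and from either source.
    """
    accl = set().union(
        *(mrg_sets(mrg_by_contrast[c]) for c in acclimation_contrasts if c in mrg_by_contrast),
        set(),
    )
    dehy = set().union(
        *(mrg_sets(mrg_by_contrast[c]) for c in dehydration_contrasts if c in mrg_by_contrast),
        set(),
    )
    out = {}
    for cat in categories:
        genes = memory_sets[cat]["up"] | memory_sets[cat]["down"]
        out[cat] = {
            "acclimation": genes & accl,
            "dehydration": genes & dehy,
            "union": genes & (accl | dehy),
        }
    return out
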