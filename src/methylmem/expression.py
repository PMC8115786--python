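"""Expression quantification and differential expression.

FPKM is computed from raw fragment counts, exonic lengths and per-library
totals. The built-in DE test is deliberately simple and fully documented: a
moment-based negative-binomial Wald test (median-of-ratios size factors,
per-gene method-of-moments dispersion with a floor, normal reference on the
log difference of group means) — external DE tables are first-class inputs
for anyone who prefers a dedicated DE package. DEG status uses the
fold-change >= 2 and adjusted p <= 0.05 rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .stats import benjamini_hochberg


def compute_fpkm(
    raw_count: float, exonic_length_bp: float, total_mapped_fragments: float
) -> float:
    """Fragments per kilobase of exon per million mapped fragments."""
    if exonic_length_bp <= 0 or total_mapped_fragments <= 0:
        raise ValueError("length and library total must be positive")
    return raw_count / (exonic_length_bp / 1e3) / (total_mapped_fragments / 1e6)


def fpkm_matrix(
    counts: pd.DataFrame,
    lengths: pd.Series,
    totals: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM for a genes x samples count matrix.

    ``totals`` defaults to the per-column count sums (all counted fragments
    mapped).
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive exonic length")
    if totals is None:
        totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("library totals must be positive")
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


def expression_class(fpkm: float) -> str:
    """Transcript-abundance class: low (<=1), medium ((1,100]), high (>100)."""
    if fpkm < 0:
        raise ValueError("FPKM must be non-negative")
    if fpkm <= 1.0:
        return "low"
    if fpkm <= 100.0:
        return "medium"
    return "high"


def expression_classes(fpkm: pd.Series) -> pd.Series:
    """Vectorised :func:`expression_class`."""
    arr = fpkm.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("FPKM must be non-negative")
    out = np.where(arr <= 1.0, "low", np.where(arr <= 100.0, "medium", "high"))
    return pd.Series(out, index=fpkm.index, name="expr_class")


# ---------------------------------------------------------------------------
# built-in DE test


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors; falls back to library-size ratios when no
    gene is observed in every sample."""
    log_counts = np.log(counts.where(counts > 0))
    log_geo = log_counts.mean(axis=1)
    usable = log_geo.notna()
    if usable.sum() >= 1:
        ratios = log_counts.sub(log_geo, axis=0)
        return np.exp(ratios[usable].median(axis=0))
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("cannot normalise: a sample has zero total counts")
    return lib / np.exp(np.log(lib).mean())


def call_de_builtin(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    lfc_threshold: float = 1.0,
    padj_threshold: float = 0.05,
    dispersion_floor: float = 0.01,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Moment-based NB Wald-type test of group B over group A, per gene.

    Returns a frame indexed by gene with log2_fc, p_value, adjusted_p and
    deg_flag. ``counts_a``/``counts_b`` are genes x replicates; both groups
    need >= 2 replicates. The log2 fold change uses a pseudo-count on
    normalised group means; all-zero genes get p = 1 and log2_fc = 0.
    """
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    genes = counts_a.index
    if not genes.equals(counts_b.index):
        raise ValueError("count matrices must share the gene index")

    combined = pd.concat([counts_a, counts_b], axis=1)
    sf = median_of_ratios_size_factors(combined)
    y = combined.div(sf, axis=1)
    na, nb = counts_a.shape[1], counts_b.shape[1]
    ya, yb = y.iloc[:, :na].to_numpy(), y.iloc[:, na:].to_numpy()

    ma, mb = ya.mean(axis=1), yb.mean(axis=1)
    va = ya.var(axis=1, ddof=1)
    vb = yb.var(axis=1, ddof=1)
    pooled_var = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    pooled_mean = (ma + mb) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (pooled_var - pooled_mean) / np.square(pooled_mean)
    disp = np.where(np.isfinite(disp), disp, dispersion_floor)
    disp = np.maximum(disp, dispersion_floor)

    # delta-method SE of log group means, stabilised by the pseudo-count
    ma_p, mb_p = ma + pseudocount, mb + pseudocount
    se2 = (ma + disp * ma**2) / (na * ma_p**2) + (mb + disp * mb**2) / (nb * mb_p**2)
    log2_fc = np.log2(mb_p) - np.log2(ma_p)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.log(mb_p) - np.log(ma_p)) / np.sqrt(se2)
    p = 2.0 * norm.sf(np.abs(z))

    all_zero = (ma == 0) & (mb == 0)
    p = np.where(all_zero | ~np.isfinite(p), 1.0, p)
    log2_fc = np.where(all_zero, 0.0, log2_fc)

    padj = benjamini_hochberg(p)
    flag = np.full(len(genes), "none", dtype=object)
    flag[(log2_fc >= lfc_threshold) & (padj <= padj_threshold)] = "up"
    flag[(log2_fc <= -lfc_threshold) & (padj <= padj_threshold)] = "down"
    return pd.DataFrame(
        {"log2_fc": log2_fc, "p_value": p, "adjusted_p": padj, "deg_flag": flag},
        index=genes,
    )


def call_de_by_contrast(
    counts: pd.DataFrame,
    design,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Built-in DE for every declared contrast of a count matrix whose
    columns are named 'condition:replicate'."""
    cond_of = pd.Index([c.split(":")[0] for c in counts.columns])
    out = {}
    for num, den, label in design.contrasts:
        ca = counts.loc[:, (cond_of == den).tolist()]
        cb = counts.loc[:, (cond_of == num).tolist()]
        out[label] = call_de_builtin(ca, cb, **kwargs)
    return out


def import_de_table(
    path,
    lfc_threshold: float = 1.0,
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Read an external DE table (TSV: gene_id, log2_fc, adjusted_p).

    The DEG flag is always recomputed from the configured thresholds, so
    external tools' own calls never leak through.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2_fc", "adjusted_p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    df = df.set_index("gene_id")
    flag = np.full(len(df), "none", dtype=object)
    up = (df["log2_fc"] >= lfc_threshold) & (df["adjusted_p"] <= padj_threshold)
    dn = (df["log2_fc"] <= -lfc_threshold) & (df["adjusted_p"] <= padj_threshold)
    flag[up.to_numpy()] = "up"
    flag[dn.to_numpy()] = "down"
    df["deg_flag"] = flag
    return df


def deg_flags(de_by_contrast: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Genes x contrasts frame of deg_flag values ('none' where absent)."""
    all_genes = pd.Index(sorted(set().union(*(d.index for d in de_by_contrast.values()))))
    cols = {}
    for label, d in de_by_contrast.items():
        cols[label] = d["deg_flag"].reindex(all_genes).fillna("none")
    return pd.DataFrame(cols, index=all_genes)
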