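"""Readers and writers for the package's on-disk formats.

Site tables, count matrices and gene lengths are plain TSV; gene models are
GFF3 (parsed with gffutils) or BED12; the comparison design round-trips
through YAML. DMRs are written both as TSV (with member positions) and BED6
(0-based half-open, score = -log10 p).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import pandas as pd
import yaml

from .types import CONTEXTS, ComparisonDesign, Dmr, GeneModel

log = logging.getLogger("methylmem")

SITE_COLUMNS = ["contig", "position", "strand", "context", "meth_count", "total_count"]


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# methylation site tables


def read_methylation_table(path: str | Path) -> pd.DataFrame:
    """Read a per-sample cytosine table (TSV, one row per covered cytosine).

    Returns a DataFrame with columns contig, position (1-based), strand,
    context, meth_count, total_count. Rows with zero coverage are dropped with
    a warning; invariant violations raise FormatError naming the line.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file without header") from exc
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = df[SITE_COLUMNS]
    if df.empty:
        return df.astype(
            {"position": int, "meth_count": int, "total_count": int}
        )

    # line numbers: header is line 1
    lines = df.index.to_numpy() + 2
    for col in ("position", "meth_count", "total_count"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            raise FormatError(f"{path}: non-numeric {col} at line {lines[bad.to_numpy()][0]}")
    df = df.astype({"position": int, "meth_count": int, "total_count": int})

    zero = (df["total_count"] == 0).to_numpy()
    if zero.any():
        log.warning("%s: dropping %d zero-coverage row(s)", path, int(zero.sum()))
        df = df[~zero]
        lines = lines[~zero]
    bad = (df["meth_count"] > df["total_count"]) | (df["meth_count"] < 0)
    if bad.any():
        raise FormatError(
            f"{path}: meth_count > total_count at line {lines[bad.to_numpy()][0]}"
        )
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        raise FormatError(f"{path}: bad context at line {lines[bad.to_numpy()][0]}")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise FormatError(f"{path}: bad strand at line {lines[bad.to_numpy()][0]}")
    return df.reset_index(drop=True)


def write_methylation_table(df: pd.DataFrame, path: str | Path) -> None:
    df[SITE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | Path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 or BED12 (format inferred from suffix).

    When a gene has several transcripts, the one with the longest summed exon
    length defines the gene-level exon structure.
    """
    path = Path(path)
    if fmt is None:
        fmt = "bed12" if path.suffix.lower() in (".bed", ".bed12") else "gff3"
    if fmt == "gff3":
        return _read_gff3(path)
    if fmt == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown gene-model format {fmt!r}")


def _read_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript")))
        best_exons: list[tuple[int, int]] = []
        if transcripts:
            for tx in transcripts:
                exons = [(e.start, e.end) for e in db.children(tx, featuretype="exon")]
                if sum(e - s + 1 for s, e in exons) > sum(
                    e - s + 1 for s, e in best_exons
                ):
                    best_exons = exons
        else:
            best_exons = [(e.start, e.end) for e in db.children(gene, featuretype="exon")]
        if not best_exons:
            best_exons = [(gene.start, gene.end)]
        for s, e in best_exons:
            if s < gene.start or e > gene.end:
                raise FormatError(f"{path}: exon ({s},{e}) outside gene {gene.id}")
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                exons=tuple(sorted(best_exons)),
            )
        )
    return genes


def _read_bed12(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}: line {ln}: BED12 needs 12 fields")
            chrom, cstart, cend, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}: line {ln}: blockCount mismatch")
            exons = [
                (cstart + off + 1, cstart + off + sz)  # BED -> 1-based inclusive
                for off, sz in zip(starts, sizes)
            ]
            if exons[-1][1] > cend:
                raise FormatError(f"{path}: line {ln}: block outside chromEnd")
            genes.append(
                GeneModel(
                    gene_id=name, contig=chrom, strand=strand,
                    start=cstart + 1, end=cend, exons=tuple(exons),
                )
            )
    return genes


def write_gene_models_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.contig}\tmethylmem\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.contig}\tmethylmem\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.contig}\tmethylmem\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# comparison design


def design_to_yaml(design: ComparisonDesign, path: str | Path) -> None:
    data = {
        "conditions": list(design.conditions),
        "contrasts": [list(c) for c in design.contrasts],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def design_from_yaml(path: str | Path) -> ComparisonDesign:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ComparisonDesign(
        conditions=tuple(data["conditions"]),
        contrasts=tuple(tuple(c) for c in data["contrasts"]),
    )


# ---------------------------------------------------------------------------
# expression matrices


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Genes x samples raw-count TSV; columns are 'condition:replicate'."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df < 0).any().any():
        raise FormatError(f"{path}: negative counts")
    return df


def write_count_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_gene_lengths(lengths: pd.Series, path: str | Path) -> None:
    lengths.rename("length_bp").to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# DMR output


def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def from_bed_interval(start0: int, end0: int) -> tuple[int, int]:
    return start0 + 1, end0


def dmrs_to_frame(dmrs: list[Dmr]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [d.contig for d in dmrs],
            "start": [d.start for d in dmrs],
            "end": [d.end for d in dmrs],
            "context": [d.context for d in dmrs],
            "direction": [d.direction for d in dmrs],
            "n_sites": [d.n_sites for d in dmrs],
            "p_value": [d.p_value for d in dmrs],
            "mean_level_num": [d.mean_level_num for d in dmrs],
            "mean_level_den": [d.mean_level_den for d in dmrs],
            "positions": [",".join(map(str, d.positions)) for d in dmrs],
        }
    )


def write_dmrs_tsv(dmrs: list[Dmr], path: str | Path) -> None:
    dmrs_to_frame(dmrs).to_csv(path, sep="\t", index=False)


def read_dmrs_tsv(path: str | Path) -> list[Dmr]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Dmr(
                contig=row.contig, start=int(row.start), end=int(row.end),
                context=row.context,
                positions=tuple(int(x) for x in str(row.positions).split(",")),
                direction=row.direction, p_value=float(row.p_value),
                mean_level_num=float(row.mean_level_num),
                mean_level_den=float(row.mean_level_den),
            )
        )
    return out


def write_dmrs_bed(dmrs: list[Dmr], path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in dmrs:
            b0, b1 = to_bed_interval(d.start, d.end)
            score = -math.log10(d.p_value) if d.p_value > 0 else 999.0
            fh.write(
                f"{d.contig}\t{b0}\t{b1}\t{d.context}:{d.direction}\t{score:.4f}\t.\n"
            )
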