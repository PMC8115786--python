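"""Domain types shared by every analysis stage.

Coordinates are 1-based inclusive throughout the package (GFF3 convention);
BED export converts to 0-based half-open at the boundary and nowhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")


@dataclass(frozen=True)
class CytosineSite:
    """Methylation evidence at one cytosine in one sample.

    ``meth_count`` of ``total_count`` aligned reads support methylation; the
    site-level methylation fraction is their ratio.
    """

    contig: str
    position: int  # 1-based
    strand: str
    context: str
    meth_count: int
    total_count: int
    sample: str = ""

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"bad context {self.context!r}")
        if self.total_count < 1:
            raise ValueError("total_count must be >= 1")
        if not 0 <= self.meth_count <= self.total_count:
            raise ValueError(
                f"meth_count {self.meth_count} outside [0, {self.total_count}]"
            )

    @property
    def level(self) -> float:
        return self.meth_count / self.total_count


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene with exon structure.

    ``start``/``end`` bound the protein-coding region; promoter and downstream
    flanks are derived on demand (strand-aware, clipped to the contig).
    """

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        exons = tuple(sorted(tuple(e) for e in self.exons)) or ((self.start, self.end),)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene span")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: overlapping/unsorted exons")
            prev_end = e

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return tuple(out)


def derive_regions(
    gene: GeneModel, flank_bp: int = 2000, contig_length: int | None = None
) -> dict[str, tuple[int, int] | None]:
    """Promoter / gene-body / downstream intervals for one gene.

    The promoter is the ``flank_bp`` bases immediately 5' of the coding region
    (upstream of ``start`` on +, downstream of ``end`` on -); ``downstream``
    mirrors it 3'. Intervals are clipped to [1, contig_length]; an interval
    clipped to nothing is returned as None.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")

    def _clip(lo: int, hi: int) -> tuple[int, int] | None:
        lo = max(lo, 1)
        if contig_length is not None:
            hi = min(hi, contig_length)
        return (lo, hi) if lo <= hi else None

    if gene.strand == "+":
        promoter = _clip(gene.start - flank_bp, gene.start - 1)
        downstream = _clip(gene.end + 1, gene.end + flank_bp)
    else:
        promoter = _clip(gene.end + 1, gene.end + flank_bp)
        downstream = _clip(gene.start - flank_bp, gene.start - 1)
    return {"promoter": promoter, "body": (gene.start, gene.end), "downstream": downstream}


@dataclass(frozen=True)
class ComparisonDesign:
    """Ordered experimental conditions plus the declared contrasts.

    A contrast is (numerator, denominator, label); by convention the label is
    "numerator/denominator" (e.g. "AD/A": acclimated-dehydrated over
    acclimated).
    """

    conditions: tuple[str, ...]
    contrasts: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        labels = [c[2] for c in self.contrasts]
        if len(set(labels)) != len(labels):
            raise ValueError("contrast labels must be unique")
        known = set(self.conditions)
        for num, den, label in self.contrasts:
            if num not in known or den not in known:
                raise ValueError(f"contrast {label}: unknown condition")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c[2] for c in self.contrasts)

    def contrast(self, label: str) -> tuple[str, str]:
        for num, den, lab in self.contrasts:
            if lab == label:
                return num, den
        raise KeyError(label)


def memory_design() -> ComparisonDesign:
    """The 13-condition acclimation / rapid-dehydration design.

    F* = fresh (non-acclimated) plants, A* = drought-acclimated plants, at the
    initial (no suffix), 4-week and 18-week growth stages; a trailing D marks
    rapid air-dehydration; SD is the slow soil-drying acclimation treatment
    itself. The eight contrasts drive DE, memory classification and the MRG
    screen.
    """
    conditions = (
        "F", "FD", "SD", "A", "AD",
        "F4", "F4D", "A4", "A4D",
        "F18", "F18D", "A18", "A18D",
    )
    pairs = [
        ("SD", "F"), ("A", "SD"), ("FD", "F"), ("AD", "A"),
        ("F4D", "F4"), ("A4D", "A4"), ("F18D", "F18"), ("A18D", "A18"),
    ]
    contrasts = tuple((n, d, f"{n}/{d}") for n, d in pairs)
    return ComparisonDesign(conditions=conditions, contrasts=contrasts)


@dataclass(frozen=True)
class Dmr:
    """A called differentially methylated region.

    ``direction`` is defined w.r.t. the contrast's numerator sample: "hyper"
    means more methylated in the numerator. ``positions`` are the member-site
    coordinates; start/end span the first to last member.
    """

    contig: str
    start: int
    end: int
    context: str
    positions: tuple[int, ...]
    direction: str  # hyper | hypo
    p_value: float
    mean_level_num: float
    mean_level_den: float

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class DeResult:
    gene_id: str
    contrast: str
    log2_fc: float
    p_value: float
    adjusted_p: float
    deg_flag: str  # up | down | none


@dataclass(frozen=True)
class MemoryCall:
    """Per-gene memory-category assignment from direction-aware set logic."""

    gene_id: str
    direction: str  # up | down
    category: str  # rdt_specific | short | mid | long | none
    preinduced_by_acclimation: bool
    support: dict[str, str] = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class MrgCall:
    """Methylation-regulated DEG call for one gene in one contrast."""

    gene_id: str
    contrast: str
    de_direction: str
    supporting_dmrs: tuple[Dmr, ...]
    is_mrg: bool


@dataclass(frozen=True)
class PhysiologySample:
    """Leaf fresh / turgid / dry weights in grams."""

    fw: float
    tw: float
    dw: float

    def __post_init__(self) -> None:
        if not self.dw <= self.fw <= self.tw:
            warnings.warn(
                f"weights violate DW <= FW <= TW ({self.dw}, {self.fw}, {self.tw}); "
                "treating as measurement noise",
                stacklevel=2,
            )


def relative_water_content(sample: PhysiologySample) -> float:
    """RWC (%) = (FW - DW) / (TW - DW) x 100."""
    if sample.tw == sample.dw:
        raise ValueError("RWC undefined: TW == DW")
    return 100.0 * (sample.fw - sample.dw) / (sample.tw - sample.dw)
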