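"""Synthetic mini-study generator with planted ground truth.

Emulates the data the analysis assumes, at desk scale: a random mini-genome
whose cytosine contexts are derived from the sequence on both strands, one
pooled WGBS library per condition (Beta-distributed true site levels, shifted
Poisson coverage, binomial methylated-read counts), and a 3-replicate
negative-binomial RNA-seq experiment over the 13-condition acclimation /
rapid-dehydration design. Promoter DMRs, DEGs, stress-memory expression
patterns and methylation-regulated genes are planted, and every planted fact
is recorded in a :class:`SimulationTruth` so downstream stages can be tested
for exact recovery.

Default context baselines (CG 0.80, CHG 0.75, CHH 0.16) sit inside the
per-sample mean-level bands the analysis targets, and mean coverage of 29x
matches the effective depth the pipeline is designed around.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ComparisonDesign, Dmr, GeneModel, derive_regions, memory_design

DEFAULT_BASELINES = {"CG": 0.80, "CHG": 0.75, "CHH": 0.16}
DEFAULT_CONCENTRATION = {"CG": 20.0, "CHG": 20.0, "CHH": 50.0}

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationParams:
    """Knobs of the synthetic study; defaults are the study conditions."""

    n_contigs: int = 2
    contig_len: int = 500_000
    n_genes: int = 200
    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    concentration: dict = field(default_factory=lambda: dict(DEFAULT_CONCENTRATION))
    coverage_mean: float = 29.0
    n_reps: int = 3
    dispersion: float = 0.1
    memory_log2fc: float = 3.0
    planted_dmr_delta: float = 0.4
    dmr_sites: int = 8
    # planted gene-category counts
    n_short: int = 12
    n_mid: int = 10
    n_long: int = 8
    n_rdt_only: int = 6
    n_plain_deg: int = 8
    # of the planted memory genes, how many also get an opposite-direction
    # promoter DMR (making them methylation-regulated memory genes)
    n_mrg_short: int = 6
    n_mrg_mid: int = 4
    n_mrg_plain: int = 5
    expression_log_mean: float = math.log(200.0)
    expression_log_sd: float = 1.5


@dataclass(frozen=True)
class PlantedRegion:
    """A methylation interval shifted in one or more conditions."""

    contig: str
    start: int
    end: int
    context: str
    positions: tuple[int, ...]
    shifts: tuple[tuple[str, float], ...]  # (condition, delta true level)
    gene_id: str | None
    role: str  # "promoter_mrg" | "free"

    def shift_for(self, condition: str) -> float:
        return dict(self.shifts).get(condition, 0.0)


@dataclass
class SimulationTruth:
    """Everything that was planted, in analysis-ready form."""

    condition_log2: pd.DataFrame  # genes x conditions expression effects
    planted_deg: pd.DataFrame  # genes x contrast labels -> up/down/none
    planted_memory_class: pd.Series  # gene -> short/mid/long/none
    planted_memory_direction: pd.Series  # gene -> up/down/"" (none)
    planted_rdt_only: set
    planted_regions: list[PlantedRegion]
    planted_mrg: dict  # contrast label -> set of gene ids
    params: SimulationParams
    seed: int

    def dmrs_for_contrast(
        self, design: ComparisonDesign, label: str
    ) -> list[Dmr]:
        """Planted regions rendered as truth-level DMR calls for a contrast."""
        num, den = design.contrast(label)
        out = []
        for r in self.planted_regions:
            delta = r.shift_for(num) - r.shift_for(den)
            if abs(delta) < 1e-12:
                continue
            out.append(
                Dmr(
                    contig=r.contig, start=r.start, end=r.end, context=r.context,
                    positions=r.positions,
                    direction="hyper" if delta > 0 else "hypo",
                    p_value=1e-9, mean_level_num=0.0, mean_level_den=0.0,
                )
            )
        return out


@dataclass
class StudyData:
    sequences: dict  # contig -> str
    genes: list
    skeleton: pd.DataFrame
    site_tables: dict  # condition -> DataFrame (site table)
    counts: pd.DataFrame  # genes x "condition:rep"
    fpkm: pd.DataFrame  # genes x condition (replicate-averaged)
    lengths: pd.Series
    design: ComparisonDesign
    truth: SimulationTruth


# ---------------------------------------------------------------------------
# genome


def _contexts_from_codes(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cytosine positions (1-based), strands and contexts from base codes.

    Codes are 0=A, 1=C, 2=G, 3=T. Cytosines within 2 bp of the relevant
    contig end (context undefined) are skipped.
    """
    n = codes.size
    pos_list, strand_list, ctx_list = [], [], []
    # + strand: C at i, context read 3' -> i+1, i+2
    ip = np.flatnonzero(codes[: n - 2] == 1)
    nxt1, nxt2 = codes[ip + 1], codes[ip + 2]
    ctx_p = np.where(nxt1 == 2, "CG", np.where(nxt2 == 2, "CHG", "CHH"))
    pos_list.append(ip + 1)
    strand_list.append(np.full(ip.size, "+"))
    ctx_list.append(ctx_p)
    # - strand: G at i is a C on the reverse strand; its 3' direction is
    # decreasing i, and complement(C)=G means "G here" reads as C there.
    im = np.flatnonzero(codes[2:] == 2) + 2
    prv1, prv2 = codes[im - 1], codes[im - 2]
    ctx_m = np.where(prv1 == 1, "CG", np.where(prv2 == 1, "CHG", "CHH"))
    pos_list.append(im + 1)
    strand_list.append(np.full(im.size, "-"))
    ctx_list.append(ctx_m)

    pos = np.concatenate(pos_list)
    order = np.argsort(pos, kind="stable")
    return (
        pos[order],
        np.concatenate(strand_list)[order],
        np.concatenate(ctx_list)[order],
    )


def simulate_genome(
    n_contigs: int,
    contig_len: int,
    n_genes: int,
    rng: np.random.Generator,
) -> tuple[dict, list, pd.DataFrame]:
    """Random genome, non-overlapping gene models and a cytosine skeleton.

    Returns (sequences, genes, skeleton); the skeleton has one row per
    cytosine on either strand with its sequence-derived context.
    """
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    frames = []
    per_contig = [n_genes // n_contigs] * n_contigs
    for i in range(n_genes % n_contigs):
        per_contig[i] += 1

    for ci in range(n_contigs):
        contig = f"ctg{ci + 1}"
        codes = rng.integers(0, 4, size=contig_len)
        sequences[contig] = "".join(_BASES[codes])
        pos, strand, ctx = _contexts_from_codes(codes)
        frames.append(
            pd.DataFrame(
                {"contig": contig, "position": pos, "strand": strand, "context": ctx}
            )
        )
        genes.extend(_place_genes(contig, contig_len, per_contig[ci], ci, rng))

    skeleton = pd.concat(frames, ignore_index=True)
    return sequences, genes, skeleton


def _place_genes(
    contig: str, contig_len: int, n: int, contig_index: int, rng: np.random.Generator
) -> list[GeneModel]:
    if n == 0:
        return []
    spans = rng.integers(600, 3001, size=n)
    margin = 2000  # keep full flanks on the contig
    min_gap = 300
    slack = contig_len - 2 * margin - int(spans.sum()) - min_gap * (n - 1)
    if slack < 0:
        raise ValueError("infeasible gene packing: contig too short")
    w = rng.random(n + 1)
    gaps = np.floor(w / w.sum() * slack).astype(int)
    genes = []
    cursor = margin + 1 + int(gaps[0])
    for gi in range(n):
        start = cursor
        end = start + int(spans[gi]) - 1
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"g{contig_index + 1}_{gi + 1:03d}"
        genes.append(
            GeneModel(
                gene_id=gene_id, contig=contig, strand=strand,
                start=start, end=end,
                exons=_random_exons(start, end, rng),
            )
        )
        cursor = end + 1 + min_gap + int(gaps[gi + 1])
    return genes


def _random_exons(start: int, end: int, rng: np.random.Generator) -> tuple:
    span = end - start + 1
    k = int(rng.integers(1, 6))
    exon_min, intron_min = 80, 50
    while k > 1 and span < k * exon_min + (k - 1) * intron_min:
        k -= 1
    if k == 1:
        return ((start, end),)
    base = k * exon_min + (k - 1) * intron_min
    extra = span - base
    w = rng.random(2 * k - 1)
    add = np.floor(w / w.sum() * extra).astype(int)
    add[0] += extra - int(add.sum())
    lens = np.array([exon_min if i % 2 == 0 else intron_min for i in range(2 * k - 1)])
    lens = lens + add
    exons = []
    cursor = start
    for i, ln in enumerate(lens):
        if i % 2 == 0:
            exons.append((cursor, cursor + int(ln) - 1))
        cursor += int(ln)
    # absorb rounding: last exon ends at gene end
    last = exons[-1]
    exons[-1] = (last[0], end)
    return tuple(exons)


# ---------------------------------------------------------------------------
# methylomes


def simulate_methylomes(
    skeleton: pd.DataFrame,
    conditions: tuple[str, ...],
    planted_regions: list[PlantedRegion],
    baselines: dict | None = None,
    concentration: dict | None = None,
    coverage_mean: float = 29.0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Per-condition site tables from Beta site levels + binomial sampling.

    Each site's true level is drawn once from a Beta centred at the context
    baseline and shared across conditions; planted regions shift the level in
    their designated conditions (clamped to [0.02, 0.98]); coverage is a
    shifted Poisson (min 1) and methylated reads binomial.
    """
    baselines = baselines or DEFAULT_BASELINES
    concentration = concentration or DEFAULT_CONCENTRATION
    rng = rng or np.random.default_rng()

    n = len(skeleton)
    base = np.empty(n)
    ctx = skeleton["context"].to_numpy()
    for c, b in baselines.items():
        mask = ctx == c
        conc = concentration[c]
        if b <= 0.0 or b >= 1.0:
            # degenerate baseline: the Beta collapses to a point mass
            base[mask] = float(np.clip(b, 0.0, 1.0))
        else:
            base[mask] = rng.beta(conc * b, conc * (1.0 - b), size=int(mask.sum()))

    # per-condition additive shifts on the true level
    shift = {cond: np.zeros(n) for cond in conditions}
    pos = skeleton["position"].to_numpy()
    contig_arr = skeleton["contig"].to_numpy()
    # contig offsets (skeleton is sorted by contig then position)
    for region in planted_regions:
        in_contig = contig_arr == region.contig
        lo = np.searchsorted(pos[in_contig], region.start, side="left")
        hi = np.searchsorted(pos[in_contig], region.end, side="right")
        idx = np.flatnonzero(in_contig)[lo:hi]
        idx = idx[ctx[idx] == region.context]
        for cond, delta in region.shifts:
            if cond not in shift:
                continue
            moved = base[idx] + delta
            if ((moved < 0.0) | (moved > 1.0)).any():
                warnings.warn(
                    f"planted shift pushes levels outside [0,1] in {region.contig}:"
                    f"{region.start}-{region.end}; clamping", stacklevel=2,
                )
            shift[cond][idx] += delta

    tables = {}
    for cond in conditions:
        level = base + shift[cond]
        shifted = shift[cond] != 0.0
        level[shifted] = np.clip(level[shifted], 0.02, 0.98)
        cov = 1 + rng.poisson(max(coverage_mean - 1.0, 0.0), size=n)
        meth = rng.binomial(cov, level)
        df = skeleton.copy()
        df["meth_count"] = meth
        df["total_count"] = cov
        tables[cond] = df
    return tables


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    genes: list,
    design: ComparisonDesign,
    condition_log2: pd.DataFrame,
    n_reps: int = 3,
    dispersion: float = 0.1,
    expression_log_mean: float = math.log(200.0),
    expression_log_sd: float = 1.5,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """NB count matrix, replicate-averaged FPKM and exonic lengths.

    ``condition_log2`` holds per-gene, per-condition log2 expression effects
    relative to the gene's baseline (0 = unperturbed).
    """
    rng = rng or np.random.default_rng()
    gene_ids = [g.gene_id for g in genes]
    lengths = pd.Series(
        [g.exonic_length for g in genes], index=gene_ids, name="length_bp"
    )
    base_mu = rng.lognormal(expression_log_mean, expression_log_sd, size=len(genes))

    cols, data = [], []
    r_nb = 1.0 / dispersion
    for cond in design.conditions:
        eff = (
            condition_log2[cond].reindex(gene_ids).fillna(0.0).to_numpy()
            if cond in condition_log2.columns
            else np.zeros(len(genes))
        )
        mu_cond = base_mu * np.power(2.0, eff)
        for rep in range(1, n_reps + 1):
            lib = rng.uniform(0.85, 1.15)
            mu = np.maximum(mu_cond * lib, 1e-8)
            p = r_nb / (r_nb + mu)
            counts = rng.negative_binomial(r_nb, p)
            cols.append(f"{cond}:{rep}")
            data.append(counts)
    counts = pd.DataFrame(
        np.column_stack(data), index=pd.Index(gene_ids, name="gene_id"), columns=cols
    )

    from .expression import fpkm_matrix  # late import to avoid a cycle

    fpkm_reps = fpkm_matrix(counts, lengths)
    cond_of = [c.split(":")[0] for c in fpkm_reps.columns]
    fpkm = fpkm_reps.T.groupby(pd.Index(cond_of, name="condition")).mean().T
    fpkm = fpkm[list(design.conditions)]
    return counts, fpkm, lengths


# ---------------------------------------------------------------------------
# planting


_MEMORY_SHIFT_CONDITIONS = {
    "short": ("SD", "AD"),
    "mid": ("SD", "AD", "A4D"),
    "long": ("SD", "AD", "A4D", "A18D"),
    "rdt": ("AD", "A4D"),
    "plain": ("FD",),
}


def _planted_deg_table(
    condition_log2: pd.DataFrame, design: ComparisonDesign
) -> pd.DataFrame:
    flags = {}
    for num, den, label in design.contrasts:
        lfc = condition_log2[num] - condition_log2[den]
        flags[label] = np.where(lfc >= 1.0, "up", np.where(lfc <= -1.0, "down", "none"))
    return pd.DataFrame(flags, index=condition_log2.index)


def simulate_study(params: SimulationParams | None = None, seed: int = 0) -> StudyData:
    """Full synthetic study: genome, methylomes, expression and truth."""
    params = params or SimulationParams()
    ss = np.random.SeedSequence(seed)
    rng_genome, rng_meth, rng_expr, rng_pick = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    design = memory_design()

    sequences, genes, skeleton = simulate_genome(
        params.n_contigs, params.contig_len, params.n_genes, rng_genome
    )
    gene_ids = [g.gene_id for g in genes]

    # ---- assign planted gene roles
    n_planted = (
        params.n_short + params.n_mid + params.n_long
        + params.n_rdt_only + params.n_plain_deg
    )
    if n_planted > params.n_genes:
        raise ValueError(
            f"cannot plant {n_planted} genes into {params.n_genes}; "
            "reduce the planted-category counts"
        )
    order = rng_pick.permutation(len(genes))
    cursor = 0

    def _take(k: int) -> list[int]:
        nonlocal cursor
        out = order[cursor : cursor + k]
        cursor += k
        return list(out)

    roles: dict[str, list[int]] = {
        "short": _take(params.n_short),
        "mid": _take(params.n_mid),
        "long": _take(params.n_long),
        "rdt": _take(params.n_rdt_only),
        "plain": _take(params.n_plain_deg),
    }

    condition_log2 = pd.DataFrame(
        0.0, index=pd.Index(gene_ids, name="gene_id"), columns=list(design.conditions)
    )
    mem_class = pd.Series("none", index=condition_log2.index)
    mem_dir = pd.Series("", index=condition_log2.index)
    for role, idxs in roles.items():
        for j, gi in enumerate(idxs):
            gid = gene_ids[gi]
            direction = 1.0 if j % 2 == 0 else -1.0
            lfc = direction * params.memory_log2fc
            for cond in _MEMORY_SHIFT_CONDITIONS[role]:
                condition_log2.loc[gid, cond] = lfc
            if role in ("short", "mid", "long"):
                mem_class[gid] = role
                mem_dir[gid] = "up" if direction > 0 else "down"

    planted_deg = _planted_deg_table(condition_log2, design)

    # ---- plant promoter methylation regions for MRG genes
    mrg_targets: list[tuple[int, str]] = []
    for role, n_mrg, shift_cond in (
        ("short", params.n_mrg_short, "AD"),
        ("mid", params.n_mrg_mid, "AD"),
        ("plain", params.n_mrg_plain, "FD"),
    ):
        for gi in roles[role][:n_mrg]:
            mrg_targets.append((gi, shift_cond))
            # memory genes are also perturbed during acclimation itself
            if role in ("short", "mid"):
                mrg_targets.append((gi, "SD"))

    planted_regions: list[PlantedRegion] = []
    skel_sorted = skeleton  # already sorted by contig, position
    for gi, cond in mrg_targets:
        gene = genes[gi]
        gid = gene.gene_id
        direction_expr = condition_log2.loc[gid, cond]
        if direction_expr == 0.0:
            continue
        # opposite-direction promoter methylation change
        delta = -params.planted_dmr_delta if direction_expr > 0 else params.planted_dmr_delta
        region = _promoter_region(
            skel_sorted, gene, params.dmr_sites, context="CG",
            shifts=((cond, delta),), role="promoter_mrg",
        )
        if region is not None:
            planted_regions.append(region)

    site_tables = simulate_methylomes(
        skeleton, design.conditions, planted_regions,
        params.baselines, params.concentration, params.coverage_mean, rng_meth,
    )
    counts, fpkm, lengths = simulate_expression(
        genes, design, condition_log2, params.n_reps, params.dispersion,
        params.expression_log_mean, params.expression_log_sd, rng_expr,
    )

    planted_mrg = _derive_mrg_truth(genes, planted_regions, planted_deg, design)
    truth = SimulationTruth(
        condition_log2=condition_log2,
        planted_deg=planted_deg,
        planted_memory_class=mem_class,
        planted_memory_direction=mem_dir,
        planted_rdt_only={gene_ids[gi] for gi in roles["rdt"]},
        planted_regions=planted_regions,
        planted_mrg=planted_mrg,
        params=params,
        seed=seed,
    )
    return StudyData(
        sequences=sequences, genes=genes, skeleton=skeleton,
        site_tables=site_tables, counts=counts, fpkm=fpkm, lengths=lengths,
        design=design, truth=truth,
    )


def _promoter_region(
    skeleton: pd.DataFrame,
    gene: GeneModel,
    n_sites: int,
    context: str,
    shifts: tuple,
    role: str,
) -> PlantedRegion | None:
    regions = derive_regions(gene)
    promoter = regions["promoter"]
    if promoter is None:
        return None
    sub = skeleton[
        (skeleton["contig"] == gene.contig)
        & (skeleton["position"] >= promoter[0])
        & (skeleton["position"] <= promoter[1])
        & (skeleton["context"] == context)
    ]
    if len(sub) < 5:
        warnings.warn(f"{gene.gene_id}: promoter has <5 {context} sites; skipping")
        return None
    positions = sub["position"].to_numpy()
    # TSS-proximal block of sites
    chosen = positions[-n_sites:] if gene.strand == "+" else positions[:n_sites]
    return PlantedRegion(
        contig=gene.contig, start=int(chosen.min()), end=int(chosen.max()),
        context=context, positions=tuple(int(p) for p in chosen),
        shifts=shifts, gene_id=gene.gene_id, role=role,
    )


def _derive_mrg_truth(
    genes: list,
    planted_regions: list[PlantedRegion],
    planted_deg: pd.DataFrame,
    design: ComparisonDesign,
) -> dict:
    """Planted MRG sets per contrast, derived geometrically from the plan.

    A gene is a planted MRG in a contrast iff it is a planted DEG there and a
    planted symmetric-context region with the opposite methylation direction
    overlaps its promoter — the noiseless form of the screening rule.
    """
    out: dict[str, set] = {label: set() for label in planted_deg.columns}
    promoters = {
        g.gene_id: (g.contig, derive_regions(g)["promoter"]) for g in genes
    }
    for num, den, label in design.contrasts:
        for region in planted_regions:
            if region.context not in ("CG", "CHG"):
                continue
            delta = region.shift_for(num) - region.shift_for(den)
            if abs(delta) < 1e-12:
                continue
            meth_dir = "hyper" if delta > 0 else "hypo"
            for g in genes:
                contig, promoter = promoters[g.gene_id]
                if promoter is None or contig != region.contig:
                    continue
                if region.end < promoter[0] or region.start > promoter[1]:
                    continue
                flag = planted_deg.loc[g.gene_id, label]
                if (flag == "up" and meth_dir == "hypo") or (
                    flag == "down" and meth_dir == "hyper"
                ):
                    out[label].add(g.gene_id)
    return out


# ---------------------------------------------------------------------------
# focused scenario generators (used by tests and the acceptance runs)


def simulate_site_pair_tables(
    n_sites: int,
    delta: float = 0.0,
    baseline: float = 0.8,
    concentration: float = 20.0,
    coverage_mean: float = 30.0,
    spacing_mean: int = 8,
    context: str = "CG",
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two single-contig site tables differing by a uniform shift ``delta``."""
    rng = rng or np.random.default_rng()
    gaps = 1 + rng.geometric(1.0 / spacing_mean, size=n_sites)
    pos = np.cumsum(gaps)
    base = rng.beta(concentration * baseline, concentration * (1 - baseline), n_sites)
    lvl_a = base
    lvl_b = np.clip(base + delta, 0.02, 0.98) if delta else base

    def _table(levels: np.ndarray) -> pd.DataFrame:
        cov = 1 + rng.poisson(coverage_mean - 1.0, n_sites)
        return pd.DataFrame(
            {
                "contig": "ctg1", "position": pos, "strand": "+",
                "context": context,
                "meth_count": rng.binomial(cov, levels), "total_count": cov,
            }
        )

    return _table(lvl_a), _table(lvl_b)


def simulate_planted_dmr_genome(
    genome_len: int = 1_000_000,
    n_regions: int = 50,
    delta: float = 0.4,
    region_sites: int = 8,
    coverage_mean: float = 30.0,
    context: str = "CG",
    baseline: float = 0.8,
    concentration: float = 20.0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[int, int, str]]]:
    """1-contig two-condition methylomes with ``n_regions`` planted DMRs.

    Returns (table_A, table_B, regions) where each region is
    (start, end, direction) and direction is the expected call in B vs A.
    Regions alternate hypo/hyper so both directions are exercised.
    """
    rng = rng or np.random.default_rng()
    seq_codes = rng.integers(0, 4, size=genome_len)
    pos, strand, ctx = _contexts_from_codes(seq_codes)
    keep = ctx == context
    pos, strand = pos[keep], strand[keep]
    n = pos.size
    base = rng.beta(concentration * baseline, concentration * (1 - baseline), n)

    lvl_b = base.copy()
    regions: list[tuple[int, int, str]] = []
    # shift toward the far side of [0,1] so the full |delta| survives clamping
    d = -delta if baseline >= 0.5 else delta
    # evenly spaced anchor sites, one planted region per stretch
    anchors = np.linspace(0, n - region_sites - 1, n_regions).astype(int)
    for a in anchors:
        sl = slice(a, a + region_sites)
        lvl_b[sl] = np.clip(base[sl] + d, 0.02, 0.98)
        regions.append(
            (int(pos[sl][0]), int(pos[sl][-1]), "hyper" if d > 0 else "hypo")
        )

    def _table(levels: np.ndarray) -> pd.DataFrame:
        cov = 1 + rng.poisson(coverage_mean - 1.0, n)
        return pd.DataFrame(
            {
                "contig": "ctg1", "position": pos, "strand": strand,
                "context": context,
                "meth_count": rng.binomial(cov, levels), "total_count": cov,
            }
        )

    return _table(base), _table(lvl_b), regions


def simulate_promoter_repression(
    n_genes: int = 200,
    repression: float = 0.1,
    rng: np.random.Generator | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Promoter levels + FPKM where the top promoter-level quartile is repressed.

    Promoter methylation is bimodal (low/high Beta mixture); genes whose
    promoter level lands above the upper quartile have their FPKM multiplied
    by ``repression``. Returns (levels, fpkm) indexed by synthetic gene ids.
    """
    rng = rng or np.random.default_rng()
    idx = pd.Index([f"g{i:04d}" for i in range(n_genes)], name="gene_id")
    high = rng.random(n_genes) < 0.5
    levels = np.where(
        high, rng.beta(40, 10, n_genes), rng.beta(4, 36, n_genes)
    )
    fpkm = rng.lognormal(math.log(20.0), 1.0, n_genes)
    upper = np.quantile(levels, 0.75)
    fpkm = np.where(levels > upper, fpkm * repression, fpkm)
    return pd.Series(levels, index=idx), pd.Series(fpkm, index=idx)
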