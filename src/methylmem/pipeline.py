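"""End-to-end orchestration of the synthetic study and all analysis stages.

``run_pipeline`` executes: simulate -> global methylation summaries ->
DMC/DMR per declared contrast -> differential expression per contrast ->
memory classification -> promoter classes and the MRG screen -> memory/MRG
intersection. Every stage writes its artifacts under the output directory so
stages can be inspected and re-run independently, and a manifest records the
seed, thresholds and per-stage row counts (no timestamps, so reruns with the
same seed are byte-identical).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import expression as xp
from . import io as mio
from . import linkage, memory, methylome
from .simulate import SimulationParams, StudyData, simulate_study
from .types import CONTEXTS

log = logging.getLogger("methylmem")


@dataclass
class RunConfig:
    """All pipeline thresholds, with the analysis defaults."""

    seed: int = 0
    outdir: str = "methylmem_run"
    simulation: SimulationParams = field(default_factory=SimulationParams)
    min_coverage: int = 4
    dmc_min_delta: float = 0.20
    dmc_alpha: float = 0.05
    dmr_seed_size: int = 5
    dmr_min_trend: int = 4
    dmr_alpha: float = 0.05
    dmr_max_gap: int = 200
    flank_bp: int = 2000
    min_region_sites: int = 3
    mc_error_rate: float = 0.005
    mc_alpha: float = 0.05
    de_lfc_threshold: float = 1.0
    de_padj_threshold: float = 0.05
    # contrasts to run DMC/DMR/MRG on; None = all declared contrasts
    dmr_contrasts: list | None = None
    # if True, memory/MRG stages consume planted truth instead of estimates
    truth_shortcut: bool = False

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        sim = data.pop("simulation", {})
        cfg = cls(**{k: v for k, v in data.items() if k in _CONFIG_FIELDS})
        cfg.simulation = SimulationParams(**sim)
        return cfg


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(RunConfig) if f.name != "simulation"}


def _slug(label: str) -> str:
    return label.replace("/", "_vs_")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    out = Path(config.outdir)
    for sub in ("inputs", "truth", "summary", "dmc", "dmr", "de", "memory", "mrg", "link"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    manifest: dict = {"seed": config.seed, "stages": {}}

    # ---- stage: simulate ---------------------------------------------------
    log.info("simulate: seed=%d", config.seed)
    study = simulate_study(config.simulation, seed=config.seed)
    _write_inputs(study, out)
    _write_truth(study, out)
    manifest["stages"]["simulate"] = {
        "n_sites": int(len(study.skeleton)),
        "n_genes": len(study.genes),
        "n_conditions": len(study.design.conditions),
        "n_planted_regions": len(study.truth.planted_regions),
    }

    # ---- stage: global summaries -------------------------------------------
    summaries = {}
    for cond in study.design.conditions:
        summaries[cond] = methylome.global_summary(
            study.site_tables[cond], config.min_coverage,
            config.mc_error_rate, config.mc_alpha,
        )
    summary_df = pd.concat(summaries, names=["sample"]).reset_index()
    summary_df.to_csv(out / "summary" / "global_summary.tsv", sep="\t", index=False)
    manifest["stages"]["summary"] = {"n_rows": int(len(summary_df))}

    # ---- stage: DMC + DMR per contrast -------------------------------------
    labels = config.dmr_contrasts or list(study.design.labels)
    dmrs_by_contrast: dict[str, list] = {}
    dmc_counts, dmr_counts = {}, {}
    for label in labels:
        num, den = study.design.contrast(label)
        pairs = methylome.pair_sites(
            study.site_tables[den], study.site_tables[num], config.min_coverage
        )
        dmcs = methylome.call_dmcs(pairs, config.dmc_min_delta, config.dmc_alpha)
        sig = dmcs[dmcs["is_dmc"]]
        sig.to_csv(out / "dmc" / f"{_slug(label)}.tsv", sep="\t", index=False)
        dmc_counts[label] = int(len(sig))

        dmrs = []
        for ctx in CONTEXTS:
            dmrs.extend(
                methylome.call_dmrs(
                    pairs, ctx, config.dmr_seed_size, config.dmr_min_trend,
                    config.dmr_alpha, config.dmr_max_gap,
                )
            )
        dmrs_by_contrast[label] = dmrs
        mio.write_dmrs_tsv(dmrs, out / "dmr" / f"{_slug(label)}.tsv")
        mio.write_dmrs_bed(dmrs, out / "dmr" / f"{_slug(label)}.bed")
        dmr_counts[label] = len(dmrs)
        log.info("contrast %s: %d DMCs, %d DMRs", label, dmc_counts[label], len(dmrs))
    manifest["stages"]["dmc"] = dmc_counts
    manifest["stages"]["dmr"] = dmr_counts

    # ---- stage: differential expression ------------------------------------
    de_by_contrast = xp.call_de_by_contrast(
        study.counts, study.design,
        lfc_threshold=config.de_lfc_threshold,
        padj_threshold=config.de_padj_threshold,
    )
    for label, de in de_by_contrast.items():
        de.to_csv(out / "de" / f"{_slug(label)}.tsv", sep="\t", index_label="gene_id")
    manifest["stages"]["de"] = {
        label: int((de["deg_flag"] != "none").sum())
        for label, de in de_by_contrast.items()
    }

    # ---- stage: memory classification --------------------------------------
    if config.truth_shortcut:
        flags = study.truth.planted_deg
    else:
        flags = xp.deg_flags(de_by_contrast)
    calls = memory.classify_memory(flags)
    memory.calls_to_frame(calls).to_csv(
        out / "memory" / "memory_calls.tsv", sep="\t"
    )
    memory.memory_summary(calls).to_csv(
        out / "memory" / "summary.tsv", sep="\t", index=False
    )
    mem_sets = memory.category_sets(calls)
    manifest["stages"]["memory"] = {
        cat: {d: len(s) for d, s in dirs.items()} for cat, dirs in mem_sets.items()
    }

    # ---- stage: promoter classes + MRG screen ------------------------------
    mrg_by_contrast: dict[str, list] = {}
    for label in labels:
        if config.truth_shortcut:
            de = pd.DataFrame(
                {"deg_flag": study.truth.planted_deg[label]},
            )
            dmrs = study.truth.dmrs_for_contrast(study.design, label)
        else:
            de = de_by_contrast[label]
            dmrs = dmrs_by_contrast[label]
        mrgs = linkage.screen_mrgs(
            de, dmrs, study.genes, label, config.flank_bp
        )
        mrg_by_contrast[label] = mrgs
        pd.DataFrame(
            {
                "gene_id": [c.gene_id for c in mrgs],
                "de_direction": [c.de_direction for c in mrgs],
                "n_supporting_dmrs": [len(c.supporting_dmrs) for c in mrgs],
                "is_mrg": [c.is_mrg for c in mrgs],
            }
        ).to_csv(out / "mrg" / f"{_slug(label)}.tsv", sep="\t", index=False)
    manifest["stages"]["mrg"] = {
        label: len(linkage.mrg_sets(calls)) for label, calls in mrg_by_contrast.items()
    }

    # promoter-methylation classes vs expression, per condition (CG context)
    link_rows = []
    for cond in study.design.conditions:
        levels = methylome.region_levels_for_genes(
            study.site_tables[cond], study.genes, "promoter", "CG",
            config.flank_bp, config.min_region_sites, config.min_coverage,
        )
        classes = linkage.classify_promoters(levels)
        test = linkage.expression_by_promoter_class(study.fpkm[cond], classes)
        link_rows.append({"sample": cond, **test})
    pd.DataFrame(link_rows).to_csv(
        out / "link" / "promoter_class_expression.tsv", sep="\t", index=False
    )

    # ---- stage: memory x MRG intersection ----------------------------------
    inter = linkage.intersect_memory_mrgs(mem_sets, mrg_by_contrast)
    rows = []
    for cat, sources in inter.items():
        for source, genes in sources.items():
            rows.append(
                {
                    "category": cat, "source": source, "n_genes": len(genes),
                    "genes": ",".join(sorted(genes)),
                }
            )
    pd.DataFrame(rows).to_csv(
        out / "link" / "memory_mrg_intersection.tsv", sep="\t", index=False
    )
    manifest["stages"]["memory_mrg"] = {
        f"{cat}:{source}": len(genes)
        for cat, sources in inter.items()
        for source, genes in sources.items()
    }

    manifest["config"] = _config_dict(config)
    manifest["versions"] = _versions()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_inputs(study: StudyData, out: Path) -> None:
    for cond, table in study.site_tables.items():
        mio.write_methylation_table(table, out / "inputs" / f"sites_{cond}.tsv")
    mio.write_gene_models_gff3(study.genes, out / "inputs" / "genes.gff3")
    mio.write_count_matrix(study.counts, out / "inputs" / "counts.tsv")
    mio.write_gene_lengths(study.lengths, out / "inputs" / "lengths.tsv")
    mio.design_to_yaml(study.design, out / "inputs" / "design.yaml")


def _write_truth(study: StudyData, out: Path) -> None:
    t = study.truth
    t.planted_deg.to_csv(out / "truth" / "planted_deg.tsv", sep="\t")
    pd.DataFrame(
        {
            "memory_class": t.planted_memory_class,
            "direction": t.planted_memory_direction,
        }
    ).to_csv(out / "truth" / "memory_class.tsv", sep="\t")
    pd.DataFrame(
        {
            "contig": [r.contig for r in t.planted_regions],
            "start": [r.start for r in t.planted_regions],
            "end": [r.end for r in t.planted_regions],
            "context": [r.context for r in t.planted_regions],
            "gene_id": [r.gene_id for r in t.planted_regions],
            "shifts": [
                ";".join(f"{c}:{d:+.2f}" for c, d in r.shifts)
                for r in t.planted_regions
            ],
        }
    ).to_csv(out / "truth" / "planted_regions.tsv", sep="\t", index=False)
    with open(out / "truth" / "planted_mrg.yaml", "w") as fh:
        yaml.safe_dump(
            {label: sorted(genes) for label, genes in t.planted_mrg.items()}, fh
        )


def _config_dict(config: RunConfig) -> dict:
    # the output location does not define the run: keep reruns into
    # different directories byte-identical
    d = dataclasses.asdict(config)
    d.pop("outdir")
    return d


def _versions() -> dict:
    import numpy
    import pandas as pd_
    import scipy

    from . import __version__

    return {
        "methylmem": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd_.__version__,
    }
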