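"""End-to-end validation benchmarks.

Each function runs one self-contained study-condition experiment — oracle
equivalence, planted-truth recovery, statistical calibration, generator
fidelity or pipeline determinism — and returns the measured quantities as a
plain dict. The test suite asserts on these numbers; the acceptance script
reports them.
"""

from __future__ import annotations

import filecmp
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import linkage, memory
from .expression import call_de_builtin
from .methylome import call_dmcs, call_dmrs, pair_sites
from .reference import brute_force_dmrs, fisher_exact_oracle
from .simulate import (
    DEFAULT_BASELINES,
    SimulationParams,
    simulate_planted_dmr_genome,
    simulate_promoter_repression,
    simulate_study,
)


def _make_pairs(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    return pair_sites(table_a, table_b, min_coverage=4)


# ---------------------------------------------------------------------------


def dmc_oracle_agreement(seed: int, n_tables: int = 10_000) -> dict:
    """Fisher DMC p-values/decisions vs per-table integer enumeration."""
    rng = np.random.default_rng(seed)
    ta = rng.integers(4, 101, n_tables)
    tb = rng.integers(4, 101, n_tables)
    ma = rng.integers(0, ta + 1)
    mb = rng.integers(0, tb + 1)
    pairs = pd.DataFrame(
        {
            "contig": "c1", "position": np.arange(n_tables), "strand": "+",
            "context": "CG",
            "meth_count_a": ma, "total_count_a": ta,
            "meth_count_b": mb, "total_count_b": tb,
        }
    )
    pairs["level_a"] = ma / ta
    pairs["level_b"] = mb / tb
    pairs["delta"] = pairs["level_b"] - pairs["level_a"]
    out = call_dmcs(pairs)
    p_oracle = np.array(
        [fisher_exact_oracle(ma[i], ta[i], mb[i], tb[i]) for i in range(n_tables)]
    )
    dec_oracle = (p_oracle < 0.05) & (np.abs(pairs["delta"].to_numpy()) >= 0.20)
    return {
        "n_tables": n_tables,
        "max_abs_p_diff": float(np.abs(out["p_value"].to_numpy() - p_oracle).max()),
        "n_decision_mismatches": int(
            (out["is_dmc"].to_numpy() != dec_oracle).sum()
        ),
    }


def dmr_reference_agreement(seed: int, n_contigs: int = 200) -> dict:
    """Production DMR scanner vs the exhaustive seed/extension reference."""
    rng = np.random.default_rng(seed)
    mismatching = 0
    n_reference_dmrs = 0
    for trial in range(n_contigs):
        n = int(rng.integers(5, 31))
        pos = np.cumsum(rng.integers(1, 320, n))
        base = rng.beta(4, 4, n)
        shift = np.zeros(n)
        if trial % 2:
            s = int(rng.integers(0, max(1, n - 6)))
            shift[s : s + int(rng.integers(5, 9))] = rng.choice([-0.45, 0.45])
        lb_true = np.clip(base + shift, 0.02, 0.98)
        cov_a = 1 + rng.poisson(20, n)
        cov_b = 1 + rng.poisson(20, n)
        context = ["CG", "CHG", "CHH"][trial % 3]
        table = {
            "contig": "c1", "position": pos, "strand": "+", "context": context,
        }
        a = pd.DataFrame({**table, "meth_count": rng.binomial(cov_a, base),
                          "total_count": cov_a})
        b = pd.DataFrame({**table, "meth_count": rng.binomial(cov_b, lb_true),
                          "total_count": cov_b})
        pairs = pair_sites(a, b, min_coverage=1)
        fast = call_dmrs(pairs, context)
        ref = brute_force_dmrs(
            pairs["position"], pairs["level_a"], pairs["level_b"],
            context=context,
        )
        n_reference_dmrs += len(ref)

        def key(dmrs):
            return [
                (d.start, d.end, d.positions, d.direction, round(d.p_value, 12))
                for d in dmrs
            ]

        if key(fast) != key(ref):
            mismatching += 1
    return {
        "n_contigs": n_contigs,
        "n_reference_dmrs": n_reference_dmrs,
        "n_mismatching_contigs": mismatching,
    }


def dmr_recovery(seed: int, alphas=(0.05, 0.01, 0.001)) -> dict:
    """Sensitivity on 50 planted DMRs in 1 Mb + null false-call rates."""
    rng = np.random.default_rng(seed)
    table_a, table_b, regions = simulate_planted_dmr_genome(rng=rng)
    pairs = _make_pairs(table_a, table_b)
    dmrs = call_dmrs(pairs, "CG")
    recovered = 0
    for start, end, direction in regions:
        hit = any(
            d.direction == direction and d.start <= end and d.end >= start
            for d in dmrs
        )
        recovered += hit
    sensitivity = recovered / len(regions)

    # matched null genome: same generator, delta = 0
    rng_null = np.random.default_rng(seed + 1)
    null_a, null_b, _ = simulate_planted_dmr_genome(delta=0.0, rng=rng_null)
    null_pairs = _make_pairs(null_a, null_b)
    genome_mb = 1.0
    false_per_mb = {}
    for alpha in alphas:
        n_false = len(call_dmrs(null_pairs, "CG", alpha=alpha))
        false_per_mb[alpha] = n_false / genome_mb
    rates = [false_per_mb[a] for a in sorted(alphas, reverse=True)]
    return {
        "n_planted": len(regions),
        "sensitivity": sensitivity,
        "false_dmrs_per_mb": false_per_mb,
        "null_rate_monotone_in_alpha": int(
            all(a >= b for a, b in zip(rates, rates[1:]))
        ),
    }


def memory_exactness(seed: int) -> dict:
    """Classifier on planted truth flags vs the planted categories."""
    study = simulate_study(SimulationParams(), seed=seed)
    truth = study.truth
    calls = memory.classify_memory(truth.planted_deg)
    got = pd.Series({c.gene_id: c.category for c in calls}).reindex(
        truth.planted_memory_class.index
    )
    planted = truth.planted_memory_class.copy()
    # rdt-only plants are expected to surface as rdt_specific, not memory
    planted[sorted(truth.planted_rdt_only)] = "rdt_specific"
    mism = int((got != planted).sum())
    # direction check on the memory genes
    dirs = {c.gene_id: c.direction for c in calls}
    for gene, cls in truth.planted_memory_class.items():
        if cls != "none" and dirs[gene] != truth.planted_memory_direction[gene]:
            mism += 1
    return {"n_genes": len(planted), "n_discrepancies": mism}


def mrg_exactness(seed: int) -> dict:
    """MRG screen + memory intersection on truth-level DMRs and DE flags."""
    study = simulate_study(SimulationParams(), seed=seed)
    truth = study.truth
    mrg_by_contrast = {}
    n_mrg_disc = 0
    for label in truth.planted_deg.columns:
        de = pd.DataFrame({"deg_flag": truth.planted_deg[label]})
        dmrs = truth.dmrs_for_contrast(study.design, label)
        calls = linkage.screen_mrgs(de, dmrs, study.genes, label)
        mrg_by_contrast[label] = calls
        got = linkage.mrg_sets(calls)
        n_mrg_disc += len(got ^ truth.planted_mrg[label])

    mem_sets = memory.category_sets(memory.classify_memory(truth.planted_deg))
    inter = linkage.intersect_memory_mrgs(mem_sets, mrg_by_contrast)
    all_planted_mrg = set().union(*truth.planted_mrg.values())
    n_inter_disc = 0
    for cat in ("short", "mid"):
        planted_cat = set(
            truth.planted_memory_class.index[truth.planted_memory_class == cat]
        )
        want = planted_cat & all_planted_mrg
        n_inter_disc += len(inter[cat]["union"] ^ want)
    return {
        "n_mrg_discrepancies": n_mrg_disc,
        "n_intersection_discrepancies": n_inter_disc,
    }


def promoter_contract(seed: int, n_genes: int = 200) -> dict:
    """Quartile tail sizes on distinct levels + planted-repression p-value."""
    rng = np.random.default_rng(seed)
    levels = pd.Series(
        rng.permutation(np.linspace(0.01, 0.99, n_genes)),
        index=[f"g{i:04d}" for i in range(n_genes)],
    )
    cls = linkage.classify_promoters(levels)
    rep_levels, rep_fpkm = simulate_promoter_repression(
        n_genes, repression=0.1, rng=rng
    )
    rep_cls = linkage.classify_promoters(rep_levels)
    test = linkage.expression_by_promoter_class(rep_fpkm, rep_cls)
    return {
        "n_genes": n_genes,
        "n_methylated": int((cls == "methylated").sum()),
        "n_unmethylated": int((cls == "unmethylated").sum()),
        "repression_p_value": float(test["p_value"]),
    }


def statistical_calibration(
    seed: int, n_null_seeds: int = 20, n_corr_seeds: int = 100
) -> dict:
    """Null calibration of the DE test and the expression/methylation r."""
    ss = np.random.SeedSequence(seed)
    de_rngs, corr_rngs = ss.spawn(2)
    rng = np.random.default_rng(de_rngs)
    fracs = []
    for _ in range(n_null_seeds):
        mu = rng.lognormal(5, 1, 2000)
        r = 1.0 / 0.1
        a = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 3))
        )
        b = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 3))
        )
        de = call_de_builtin(a, b)
        fracs.append(float((de["adjusted_p"] <= 0.05).mean()))

    rng = np.random.default_rng(corr_rngs)
    n_small = 0
    for _ in range(n_corr_seeds):
        idx = [f"g{i}" for i in range(1000)]
        de = pd.DataFrame(
            {"log2_fc": rng.normal(0, 2, 1000), "deg_flag": "none"}, index=idx
        )
        delta = pd.Series(rng.normal(0, 0.2, 1000), index=idx)
        r_val = linkage.correlate_fc_vs_promoter_delta(de, delta)["all_genes"]["r"]
        n_small += abs(r_val) < 0.1
    return {
        "mean_null_bh_fraction": float(np.mean(fracs)),
        "n_de_null_seeds": n_null_seeds,
        "null_corr_frac_below_0.1": n_small / n_corr_seeds,
        "n_corr_seeds": n_corr_seeds,
    }


def generator_fidelity(seed: int) -> dict:
    """Per-context empirical mean levels vs the configured Beta targets."""
    study = simulate_study(SimulationParams(), seed=seed)
    table = study.site_tables["F"]
    out = {}
    for ctx, target in DEFAULT_BASELINES.items():
        sub = table[table["context"] == ctx]
        mean = float((sub["meth_count"] / sub["total_count"]).mean())
        out[ctx] = {
            "n_sites": int(len(sub)),
            "mean_level_pct": 100.0 * mean,
            "target_pct": 100.0 * target,
            "abs_error_pct": abs(100.0 * mean - 100.0 * target),
        }
    return out


def pipeline_determinism(seed: int, workdir: str | None = None) -> dict:
    """Two full default runs with the same seed, compared byte for byte."""
    from .pipeline import RunConfig, run_pipeline

    base = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="methylmem_"))
    out1, out2 = base / "run1", base / "run2"
    run_pipeline(RunConfig(seed=seed, outdir=str(out1)))
    run_pipeline(RunConfig(seed=seed, outdir=str(out2)))

    n_files = 0
    identical = True

    def walk(dc: filecmp.dircmp):
        nonlocal identical, n_files
        n_files += len(dc.common_files)
        if dc.diff_files or dc.left_only or dc.right_only or dc.funny_files:
            identical = False
        for sub in dc.subdirs.values():
            walk(sub)

    walk(filecmp.dircmp(out1, out2))
    # dircmp's default comparison is stat-based; confirm content equality
    if identical:
        match, mismatch, errors = filecmp.cmpfiles(
            out1, out2, _all_files(out1), shallow=False
        )
        if mismatch or errors:
            identical = False
    return {"identical": int(identical), "n_files_compared": n_files}


def _all_files(root: Path) -> list[str]:
    return [str(p.relative_to(root)) for p in root.rglob("*") if p.is_file()]
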