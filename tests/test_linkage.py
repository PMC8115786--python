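"""Promoter classes, expression coupling, correlations and the MRG screen."""

import numpy as np
import pandas as pd
import pytest

from methylmem.linkage import (
    classify_promoters,
    correlate_fc_vs_promoter_delta,
    correlate_pathway_genes,
    expression_by_promoter_class,
    intersect_memory_mrgs,
    mrg_sets,
    screen_mrgs,
)
from methylmem.simulate import simulate_promoter_repression
from methylmem.types import Dmr, GeneModel


class TestClassifyPromoters:
    def test_eight_distinct_levels_give_two_per_tail(self):
        levels = pd.Series(np.arange(8) / 10.0, index=[f"g{i}" for i in range(8)])
        cls = classify_promoters(levels)
        assert (cls == "methylated").sum() == 2
        assert (cls == "unmethylated").sum() == 2

    def test_identical_levels_all_intermediate(self):
        levels = pd.Series(0.5, index=[f"g{i}" for i in range(10)])
        assert (classify_promoters(levels) == "intermediate").all()

    def test_nan_levels_are_missing(self):
        levels = pd.Series(np.arange(9) / 10.0, index=[f"g{i}" for i in range(9)])
        levels["g4"] = np.nan
        cls = classify_promoters(levels)
        assert cls["g4"] == "missing"

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            classify_promoters(pd.Series([0.1] * 7))

    def test_bimodal_plant_recovered(self):
        rng = np.random.default_rng(16)
        levels, _ = simulate_promoter_repression(400, rng=rng)
        cls = classify_promoters(levels)
        planted_high = levels > np.quantile(levels, 0.75)
        agree = (cls[planted_high] == "methylated").mean()
        assert agree >= 0.95

    def test_tail_sizes_bounded(self):
        rng = np.random.default_rng(17)
        levels = pd.Series(rng.random(101), index=[f"g{i}" for i in range(101)])
        cls = classify_promoters(levels)
        bound = int(np.ceil(101 / 4))
        assert (cls == "methylated").sum() <= bound
        assert (cls == "unmethylated").sum() <= bound


class TestExpressionByPromoterClass:
    def _classes(self, n):
        half = n // 2
        return pd.Series(
            ["methylated"] * half + ["unmethylated"] * (n - half),
            index=[f"g{i}" for i in range(n)],
        )

    def test_copied_distribution_gives_p_one(self):
        vals = [1.0, 3.0, 7.0, 20.0, 55.0]
        fpkm = pd.Series(vals + vals, index=[f"g{i}" for i in range(10)])
        out = expression_by_promoter_class(fpkm, self._classes(10))
        assert out["p_value"] == 1.0

    def test_label_swap_preserves_p(self):
        rng = np.random.default_rng(18)
        fpkm = pd.Series(rng.lognormal(2, 1, 20), index=[f"g{i}" for i in range(20)])
        cls = self._classes(20)
        swapped = cls.map({"methylated": "unmethylated", "unmethylated": "methylated"})
        a = expression_by_promoter_class(fpkm, cls)
        b = expression_by_promoter_class(fpkm, swapped)
        assert a["p_value"] == pytest.approx(b["p_value"])

    def test_planted_repression_detected(self):
        rng = np.random.default_rng(19)
        levels, fpkm = simulate_promoter_repression(200, repression=0.1, rng=rng)
        cls = classify_promoters(levels)
        out = expression_by_promoter_class(fpkm, cls)
        assert out["p_value"] < 1e-3
        assert out["median_methylated"] < out["median_unmethylated"]

    def test_empty_class_is_missing_result(self):
        fpkm = pd.Series([1.0, 2.0], index=["g0", "g1"])
        cls = pd.Series(["methylated", "intermediate"], index=["g0", "g1"])
        assert np.isnan(expression_by_promoter_class(fpkm, cls)["p_value"])


class TestCorrelations:
    def test_perfect_line_gives_minus_one(self):
        idx = [f"g{i}" for i in range(20)]
        de = pd.DataFrame(
            {"log2_fc": np.linspace(-3, 3, 20), "deg_flag": "up"}, index=idx
        )
        delta = pd.Series(-0.1 * de["log2_fc"], index=idx)
        out = correlate_fc_vs_promoter_delta(de, delta)
        assert out["all_genes"]["r"] == pytest.approx(-1.0)

    def test_constant_delta_is_missing(self):
        idx = [f"g{i}" for i in range(10)]
        de = pd.DataFrame({"log2_fc": np.arange(10.0), "deg_flag": "none"}, index=idx)
        out = correlate_fc_vs_promoter_delta(de, pd.Series(0.3, index=idx))
        assert np.isnan(out["all_genes"]["r"])

    def test_independent_quantities_rarely_correlate(self):
        rng = np.random.default_rng(20)
        small = 0
        for _ in range(40):
            idx = [f"g{i}" for i in range(1000)]
            de = pd.DataFrame(
                {"log2_fc": rng.normal(0, 2, 1000), "deg_flag": "none"}, index=idx
            )
            delta = pd.Series(rng.normal(0, 0.2, 1000), index=idx)
            r = correlate_fc_vs_promoter_delta(de, delta)["all_genes"]["r"]
            small += abs(r) < 0.1
        assert small / 40 >= 0.95

    def test_pathway_identity_metric(self):
        metrics = pd.DataFrame(
            {"cg_level": [70.0, 75.0, 80.0, 85.0]}, index=list("abcd")
        )
        expr = pd.DataFrame({"MET1": [70.0, 75.0, 80.0, 85.0]}, index=list("abcd"))
        out = correlate_pathway_genes(metrics, expr)
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert bool(out.loc[0, "significant"])

    def test_pathway_anticorrelation_recovered(self):
        rng = np.random.default_rng(21)
        x = rng.random(8) * 10 + 70
        metrics = pd.DataFrame({"m": x}, index=[f"s{i}" for i in range(8)])
        expr = pd.DataFrame(
            {"DRM2": -2 * x + rng.normal(0, 0.5, 8)}, index=metrics.index
        )
        out = correlate_pathway_genes(metrics, expr)
        assert out.loc[0, "r"] < -0.9

    def test_too_few_samples_rejected(self):
        m = pd.DataFrame({"m": [1.0, 2.0]}, index=["a", "b"])
        e = pd.DataFrame({"g": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            correlate_pathway_genes(m, e)

    def test_degenerate_n3_perfect_correlation_warns(self):
        m = pd.DataFrame({"m": [1.0, 2.0, 3.0]}, index=list("abc"))
        e = pd.DataFrame({"g": [2.0, 4.0, 6.0]}, index=list("abc"))
        with pytest.warns(UserWarning, match="insufficient n"):
            out = correlate_pathway_genes(m, e)
        assert out.loc[0, "r"] == pytest.approx(1.0)


def _dmr(contig, start, end, context, direction):
    return Dmr(
        contig=contig, start=start, end=end, context=context,
        positions=tuple(range(start, end + 1, 50)), direction=direction,
        p_value=1e-4, mean_level_num=0.5, mean_level_den=0.2,
    )


class TestScreenMrgs:
    def _gene(self, strand="+"):
        return GeneModel("g1", "c1", strand, 5001, 7000)

    def _de(self, flag):
        return pd.DataFrame({"deg_flag": [flag]}, index=["g1"])

    def test_up_gene_with_promoter_hypo_dmr(self):
        dmr = _dmr("c1", 4000, 4400, "CG", "hypo")
        calls = screen_mrgs(self._de("up"), [dmr], [self._gene()], "AD/A")
        assert mrg_sets(calls) == {"g1"}

    def test_chh_context_does_not_count(self):
        dmr = _dmr("c1", 4000, 4400, "CHH", "hypo")
        calls = screen_mrgs(self._de("up"), [dmr], [self._gene()], "AD/A")
        assert mrg_sets(calls) == set()

    def test_direction_must_oppose_expression(self):
        dmr = _dmr("c1", 4000, 4400, "CG", "hyper")
        calls = screen_mrgs(self._de("up"), [dmr], [self._gene()], "AD/A")
        assert mrg_sets(calls) == set()

    def test_promoter_is_strand_aware(self):
        # same DMR interval; for a - strand gene the promoter is 3' of end
        dmr = _dmr("c1", 7100, 7500, "CHG", "hypo")
        plus = screen_mrgs(self._de("up"), [dmr], [self._gene("+")], "AD/A")
        minus = screen_mrgs(self._de("up"), [dmr], [self._gene("-")], "AD/A")
        assert mrg_sets(plus) == set()
        assert mrg_sets(minus) == {"g1"}

    def test_adding_qualifying_dmr_is_monotone(self):
        rng = np.random.default_rng(22)
        genes = [
            GeneModel(f"g{i}", "c1", "+", 5001 + i * 10_000, 7000 + i * 10_000)
            for i in range(20)
        ]
        de = pd.DataFrame(
            {"deg_flag": rng.choice(["up", "down", "none"], 20)},
            index=[g.gene_id for g in genes],
        )
        dmrs = [
            _dmr("c1", 3500 + i * 10_000, 3900 + i * 10_000, "CG",
                 rng.choice(["hyper", "hypo"]))
            for i in range(0, 20, 2)
        ]
        before = mrg_sets(screen_mrgs(de, dmrs, genes, "AD/A"))
        extra = _dmr("c1", 3500 + 10_000, 3900 + 10_000, "CG",
                     "hypo" if de.loc["g1", "deg_flag"] == "up" else "hyper")
        after = mrg_sets(screen_mrgs(de, dmrs + [extra], genes, "AD/A"))
        assert before <= after

    def test_planted_truth_recovered_exactly(self, study):
        """Truth-level DMRs + truth DE flags reproduce the planted MRG sets."""
        truth = study.truth
        for label in truth.planted_deg.columns:
            de = pd.DataFrame({"deg_flag": truth.planted_deg[label]})
            dmrs = truth.dmrs_for_contrast(study.design, label)
            got = mrg_sets(screen_mrgs(de, dmrs, study.genes, label))
            assert got == truth.planted_mrg[label], label


class TestIntersectMemoryMrgs:
    def _memory_sets(self):
        return {
            "short": {"up": {"g1", "g2"}, "down": set()},
            "mid": {"up": {"g3"}, "down": {"g4"}},
        }

    def _mrg(self, label, genes):
        return [
            type("C", (), {"gene_id": g, "is_mrg": True})() for g in genes
        ]

    def test_mid_gene_in_acclimation_source(self):
        mrgs = {"SD/F": self._mrg("SD/F", ["g3"]), "AD/A": self._mrg("AD/A", [])}
        out = intersect_memory_mrgs(self._memory_sets(), mrgs)
        assert out["mid"]["acclimation"] == {"g3"}
        assert out["mid"]["dehydration"] == set()
        assert out["mid"]["union"] == {"g3"}

    def test_non_memory_gene_excluded(self):
        mrgs = {"AD/A": self._mrg("AD/A", ["g9"])}
        out = intersect_memory_mrgs(self._memory_sets(), mrgs)
        assert out["short"]["union"] == set()

    def test_planted_intersection_recovered(self, study):
        """Truth-level run reproduces the planted memory-MRG overlap."""
        from methylmem.memory import category_sets, classify_memory

        truth = study.truth
        mem_sets = category_sets(classify_memory(truth.planted_deg))
        mrg_by_contrast = {}
        for label in truth.planted_deg.columns:
            de = pd.DataFrame({"deg_flag": truth.planted_deg[label]})
            dmrs = truth.dmrs_for_contrast(study.design, label)
            mrg_by_contrast[label] = screen_mrgs(de, dmrs, study.genes, label)
        out = intersect_memory_mrgs(mem_sets, mrg_by_contrast)

        # expected: planted short/mid genes that are planted MRGs in any source
        all_planted_mrg = set().union(*truth.planted_mrg.values())
        for cat in ("short", "mid"):
            planted_cat = set(
                truth.planted_memory_class.index[truth.planted_memory_class == cat]
            )
            assert out[cat]["union"] == planted_cat & all_planted_mrg, cat
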