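"""Methylome statistics: levels, mC calls, DMCs, the DMR scanner, regions."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_site_table
from methylmem.methylome import (
    call_dmc,
    call_dmcs,
    call_dmrs,
    call_mc_site,
    global_summary,
    metagene_profile,
    pair_sites,
    region_levels_for_genes,
    region_methylation,
    site_level,
)
from methylmem.reference import brute_force_dmrs, fisher_exact_oracle, validate_dmr
from methylmem.types import GeneModel


class TestSiteLevel:
    @pytest.mark.parametrize(
        "meth,total,expected", [(15, 20, 0.75), (0, 30, 0.0), (30, 30, 1.0)]
    )
    def test_arithmetic(self, meth, total, expected):
        assert site_level(meth, total) == expected

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            site_level(0, 0)


class TestCallMcSite:
    def test_unmethylated_site(self):
        assert not call_mc_site(0, 20)

    def test_saturated_site(self):
        assert call_mc_site(20, 20)

    @pytest.mark.parametrize("meth", [0, 1, 2, 3])
    def test_decision_matches_binomial_tail_enumeration(self, meth):
        """Decision equals a direct tail sum P(X >= meth | n, error_rate)."""
        from math import comb

        n, e = 20, 0.005
        tail = sum(
            comb(n, k) * e**k * (1 - e) ** (n - k) for k in range(meth, n + 1)
        )
        assert call_mc_site(meth, n) == (tail < 0.05)


class TestGlobalSummary:
    def test_fully_methylated_sample(self):
        sites = make_site_table([10, 20, 30], [20, 20, 20], [20, 20, 20])
        out = global_summary(sites)
        assert out.loc["CG", "mc_frequency_pct"] == 100.0
        assert out.loc["CG", "mean_level_mc_pct"] == 100.0

    def test_absent_context_reported_missing(self):
        sites = make_site_table([10], [20], [20], context="CG")
        out = global_summary(sites)
        assert np.isnan(out.loc["CHH", "mc_frequency_pct"])
        assert out.loc["CG", "n_covered"] == 1

    def test_coverage_filter_applies(self):
        sites = make_site_table([10, 20], [2, 20], [3, 20])
        out = global_summary(sites, min_coverage=4)
        assert out.loc["CG", "n_covered"] == 1

    def test_generator_levels_land_in_target_band(self, study):
        """Simulated CG mean level falls in the band the defaults target."""
        out = global_summary(study.site_tables["F"])
        assert 75.75 <= out.loc["CG", "mean_level_mc_pct"] <= 84.32


class TestCallDmc:
    def test_identical_counts_not_dmc(self):
        is_dmc, p, _ = call_dmc(10, 20, 10, 20)
        assert not is_dmc and p == 1.0

    def test_large_change_is_dmc_with_enumerated_p(self):
        is_dmc, p, direction = call_dmc(18, 20, 2, 20)
        assert is_dmc and direction == "hypo"
        assert p == pytest.approx(fisher_exact_oracle(18, 20, 2, 20), abs=1e-12)

    def test_small_delta_never_dmc(self):
        # |delta| = 0.15 fails the 20% rule regardless of p
        is_dmc, _, _ = call_dmc(10, 20, 7, 20)
        assert not is_dmc

    def test_batch_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(4)
        n = 1000
        ta = rng.integers(4, 101, n)
        tb = rng.integers(4, 101, n)
        ma = rng.integers(0, ta + 1)
        mb = rng.integers(0, tb + 1)
        pairs = pd.DataFrame(
            {
                "contig": "c1", "position": np.arange(n), "strand": "+",
                "context": "CG",
                "meth_count_a": ma, "total_count_a": ta,
                "meth_count_b": mb, "total_count_b": tb,
            }
        )
        pairs["level_a"] = ma / ta
        pairs["level_b"] = mb / tb
        pairs["delta"] = pairs["level_b"] - pairs["level_a"]
        out = call_dmcs(pairs)
        want = np.array(
            [fisher_exact_oracle(ma[i], ta[i], mb[i], tb[i]) for i in range(n)]
        )
        np.testing.assert_allclose(out["p_value"].to_numpy(), want, atol=1e-12)


def _paired_tables(pos, la, lb, coverage=30):
    """Site tables whose observed levels are exactly la/lb at fixed coverage."""
    meth_a = np.rint(np.asarray(la) * coverage).astype(int)
    meth_b = np.rint(np.asarray(lb) * coverage).astype(int)
    a = make_site_table(pos, meth_a, [coverage] * len(pos))
    b = make_site_table(pos, meth_b, [coverage] * len(pos))
    return pair_sites(a, b, min_coverage=1)


class TestCallDmrs:
    def test_null_data_yields_nothing(self):
        pos = np.arange(100, 700, 50)
        la = [0.5] * len(pos)
        pairs = _paired_tables(pos, la, la)
        assert call_dmrs(pairs, "CG") == []

    def test_six_site_instance_matches_reference(self):
        pos = [100, 150, 200, 250, 300, 350]
        la, lb = [0.1] * 6, [0.9] * 6
        pairs = _paired_tables(pos, la, lb)
        (dmr,) = call_dmrs(pairs, "CG")
        assert dmr.direction == "hyper"
        assert dmr.positions == tuple(pos)
        (ref,) = brute_force_dmrs(pos, la, lb)
        assert (dmr.start, dmr.end, dmr.p_value) == (ref.start, ref.end, ref.p_value)

    def test_wide_gap_blocks_seeding(self):
        pos = [100, 150, 200, 700, 750, 800]  # 500-bp gap splits the run
        pairs = _paired_tables(pos, [0.1] * 6, [0.9] * 6)
        assert call_dmrs(pairs, "CG") == []

    def test_fewer_sites_than_seed_is_no_error(self):
        pairs = _paired_tables([100, 150], [0.1, 0.1], [0.9, 0.9])
        assert call_dmrs(pairs, "CG") == []

    def test_swapping_samples_flips_direction_only(self):
        rng = np.random.default_rng(8)
        pos = np.cumsum(rng.integers(10, 100, 40))
        base = rng.beta(4, 4, 40)
        lb = np.clip(base + np.where(np.arange(40) % 13 < 7, 0.5, 0.0), 0, 0.98)
        fwd = call_dmrs(_paired_tables(pos, base, lb), "CG")
        rev = call_dmrs(_paired_tables(pos, lb, base), "CG")
        assert len(fwd) > 0
        assert [(d.start, d.end, d.p_value) for d in fwd] == [
            (d.start, d.end, d.p_value) for d in rev
        ]
        flip = {"hyper": "hypo", "hypo": "hyper"}
        assert [flip[d.direction] for d in fwd] == [d.direction for d in rev]

    def test_randomized_contigs_match_brute_force(self):
        """Scanner output identical to the exhaustive reference."""
        rng = np.random.default_rng(9)
        n_dmrs = 0
        for trial in range(60):
            n = int(rng.integers(5, 31))
            pos = np.cumsum(rng.integers(1, 320, n))
            base = rng.beta(4, 4, n)
            shift = np.zeros(n)
            if trial % 2:
                s = int(rng.integers(0, max(1, n - 6)))
                shift[s : s + int(rng.integers(5, 9))] = rng.choice([-0.45, 0.45])
            lb = np.clip(base + shift, 0.02, 0.98)
            cov_a = 1 + rng.poisson(20, n)
            cov_b = 1 + rng.poisson(20, n)
            a = make_site_table(pos, rng.binomial(cov_a, base), cov_a)
            b = make_site_table(pos, rng.binomial(cov_b, lb), cov_b)
            pairs = pair_sites(a, b, min_coverage=1)
            fast = call_dmrs(pairs, "CG")
            ref = brute_force_dmrs(
                pairs["position"], pairs["level_a"], pairs["level_b"]
            )
            n_dmrs += len(ref)

            def key(dmrs):
                return [
                    (d.start, d.end, d.positions, d.direction, round(d.p_value, 12))
                    for d in dmrs
                ]

            assert key(fast) == key(ref)
        assert n_dmrs > 5  # the comparison exercised real calls

    def test_emitted_dmrs_satisfy_invariants(self):
        rng = np.random.default_rng(10)
        n = 200
        pos = np.cumsum(rng.integers(5, 60, n))
        base = rng.beta(4, 4, n)
        lb = np.clip(base + np.where((np.arange(n) // 10) % 3 == 0, -0.5, 0.0), 0.02, 1)
        pairs = _paired_tables(pos, base, lb)
        dmrs = call_dmrs(pairs, "CG")
        assert dmrs
        for d in dmrs:
            problems = validate_dmr(
                d, pairs["position"].tolist(),
                pairs["level_a"].tolist(), pairs["level_b"].tolist(),
            )
            assert problems == []


class TestRegionMethylation:
    def test_mean_of_two_sites(self):
        sites = make_site_table([100, 200], [4, 16], [20, 20])
        level, n = region_methylation(sites, "c1", (50, 250), "CG", min_sites=2)
        assert level == pytest.approx(0.5)
        assert n == 2

    def test_empty_region_is_missing(self):
        sites = make_site_table([100], [4], [20])
        level, n = region_methylation(sites, "c1", (500, 600), "CG")
        assert np.isnan(level) and n == 0

    def test_min_sites_rule(self):
        sites = make_site_table([100, 200], [4, 16], [20, 20])
        level, _ = region_methylation(sites, "c1", (50, 250), "CG", min_sites=3)
        assert np.isnan(level)

    def test_simulated_sites_recover_beta_mean(self):
        rng = np.random.default_rng(12)
        n = 1000
        cov = 1 + rng.poisson(28, n)
        meth = rng.binomial(cov, rng.beta(16, 4, n))
        sites = make_site_table(np.arange(1, n + 1) * 3, meth, cov)
        level, _ = region_methylation(sites, "c1", (1, 10**6), "CG")
        assert level == pytest.approx(0.8, abs=0.03)

    def test_region_levels_for_genes_vectorised(self):
        sites = make_site_table([900, 950, 1000, 5000], [20, 10, 0, 20], [20, 20, 20, 20])
        gene = GeneModel("g", "c1", "+", 1001, 2000)
        levels = region_levels_for_genes(sites, [gene], "promoter", "CG", 2000, 3)
        # promoter (1,1000) catches the first three sites: (1.0+0.5+0.0)/3
        assert levels["g"] == pytest.approx(0.5)


class TestMetageneProfile:
    def _uniform_sites(self, level=0.5):
        pos = np.arange(100, 9000, 37)
        cov = 20
        return make_site_table(pos, [int(level * cov)] * len(pos), [cov] * len(pos))

    def test_uniform_levels_give_flat_profile(self):
        gene = GeneModel("g", "c1", "+", 3001, 5000)
        classes = pd.Series({"g": "medium"})
        prof = metagene_profile(self._uniform_sites(), [gene], classes)
        assert (prof["mean_level"] == 0.5).all()
        # single-exon gene: every body site is exonic
        assert set(prof["segment"]) == {"upstream", "exon", "downstream"}

    def test_minus_strand_mirrors_plus_strand(self):
        L = 12_000
        pos = np.arange(100, L - 100, 53)
        levels = (pos % 1000) / 1000.0
        cov = 100
        fwd_sites = make_site_table(pos, np.rint(levels * cov).astype(int), [cov] * len(pos))
        mirror_pos = L + 1 - pos
        order = np.argsort(mirror_pos)
        rev_sites = make_site_table(
            mirror_pos[order], np.rint(levels * cov).astype(int)[order], [cov] * len(pos)
        )
        g_fwd = GeneModel("g", "c1", "+", 4001, 6000)
        g_rev = GeneModel("g", "c1", "-", L + 1 - 6000, L + 1 - 4001)
        classes = pd.Series({"g": "low"})
        p_fwd = metagene_profile(fwd_sites, [g_fwd], classes)
        p_rev = metagene_profile(rev_sites, [g_rev], classes)
        pd.testing.assert_frame_equal(p_fwd, p_rev)

    def test_planted_promoter_hypermethylation_separates_classes(self):
        rng = np.random.default_rng(13)
        genes, frames = [], []
        for i in range(40):
            offset = i * 10_000
            start, end = offset + 3001, offset + 5000
            cls = "low" if i % 2 == 0 else "high"
            genes.append(GeneModel(f"g{i}", "c1", "+", start, end))
            pos = np.arange(offset + 500, offset + 7500, 23)
            promoter_hyper = (pos >= start - 2000) & (pos < start) & (cls == "low")
            level = np.where(promoter_hyper, 0.85, 0.15)
            cov = 30
            meth = rng.binomial(cov, level)
            frames.append(make_site_table(pos, meth, [cov] * len(pos)))
        sites = pd.concat(frames, ignore_index=True)
        classes = pd.Series({g.gene_id: ("low" if i % 2 == 0 else "high") for i, g in enumerate(genes)})
        prof = metagene_profile(sites, genes, classes)
        up = prof[(prof["segment"] == "upstream") & (prof["context"] == "CG")]
        lo = up[up["expr_class"] == "low"].set_index("bin")["mean_level"]
        hi = up[up["expr_class"] == "high"].set_index("bin")["mean_level"]
        n_exceed = int((lo > hi.reindex(lo.index)).sum())
        assert n_exceed >= 18
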