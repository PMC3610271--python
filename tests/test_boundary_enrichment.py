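"""Boundary/site co-localization statistics and random controls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chiptools import (GenomeTable, match_sites_to_boundaries,
                       colocalize_boundaries, classify_vs_genes,
                       sample_random_sites, enrichment_test,
                       nearest_distance_distribution, lamina_alignment,
                       truncate_pct, GeneRecord, CorrelationParams)
from .oracles import binom_sf_exact


def bnd(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "polarity"])


def sites_at(positions, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions})


class TestMatchSites:
    def test_site_at_boundary_rich_side(self):
        out = match_sites_to_boundaries(bnd([("chr1", 1000, "+")]), sites_at([1000]))
        row = out.iloc[0]
        assert row["matched"] and row["distance"] == 0 and row["side"] == "rich"

    def test_polarity_arithmetic(self):
        # 1 kb into the rich side of a rich-right boundary
        out = match_sites_to_boundaries(bnd([("chr1", 5000, "+")]), sites_at([6000]))
        assert out.iloc[0]["distance"] == 1000 and out.iloc[0]["side"] == "rich"
        # same site relative to a rich-left boundary lies on the poor side
        out = match_sites_to_boundaries(bnd([("chr1", 5000, "-")]), sites_at([6000]))
        assert out.iloc[0]["distance"] == -1000 and out.iloc[0]["side"] == "poor"

    def test_radius_is_closed(self):
        out = match_sites_to_boundaries(bnd([("chr1", 5000, "+")]),
                                        sites_at([7500, 20_000]), radius=2500)
        assert bool(out.iloc[0]["matched"])
        out = match_sites_to_boundaries(bnd([("chr1", 5000, "+")]),
                                        sites_at([7501]), radius=2500)
        assert not out.iloc[0]["matched"]

    def test_rich_side_planting_detected(self):
        rng = np.random.default_rng(0)
        boundaries = bnd([("chr1", int(p), "+") for p in
                          np.arange(200) * 50_000 + 10_000])
        planted = sites_at(boundaries["pos"] + rng.integers(0, 2000, size=200))
        out = match_sites_to_boundaries(boundaries, planted)
        k_rich = int((out["side"] == "rich").sum())
        k_poor = int((out["side"] == "poor").sum())
        p = stats.binomtest(k_rich, k_rich + k_poor, 0.5,
                            alternative="greater").pvalue
        assert p < 1e-6


class TestColocalize:
    def test_identical_lists_opposite_polarity_zero_pairs(self):
        a = bnd([("chr1", p, "+") for p in np.arange(10) * 100_000])
        pairs, unmatched = colocalize_boundaries(a, a, radius=2500,
                                                 require_opposite_polarity=True)
        assert len(pairs) == 0 and len(unmatched) == 10

    def test_disjoint_chromosomes_zero_pairs(self):
        a = bnd([("chr1", 100, "+")])
        b = bnd([("chr2", 100, "-")])
        pairs, _ = colocalize_boundaries(a, b)
        assert len(pairs) == 0

    def test_one_to_one_greedy_by_distance(self):
        a = bnd([("chr1", 10_000, "+"), ("chr1", 10_400, "+")])
        b = bnd([("chr1", 10_100, "-")])
        pairs, unmatched = colocalize_boundaries(a, b, radius=2500)
        assert len(pairs) == 1
        assert pairs.iloc[0]["a_index"] == 0 and pairs.iloc[0]["distance"] == 100
        assert list(unmatched) == [1]

    def test_planted_double_boundaries_recovered(self):
        from chiptools import SimulationParams, make_double_boundary_locus
        locus = make_double_boundary_locus(SimulationParams(seed=3))
        k27_b, k36_b = locus["k27"][2], locus["k36"][2]
        pairs, unmatched = colocalize_boundaries(k27_b, k36_b, radius=2500,
                                                 require_opposite_polarity=True)
        assert len(pairs) == 2 and len(unmatched) == 0
        assert (pairs["distance"] == 0).all()


class TestClassifyVsGenes:
    GENES = [GeneRecord(id="g1", chrom="chr1", tss=50_000, tes=60_000, strand="+"),
             GeneRecord(id="g2", chrom="chr1", tss=95_000, tes=85_000, strand="-")]

    def test_tss_within_radius(self):
        cls = classify_vs_genes(bnd([("chr1", 51_000, "+")]), self.GENES)
        assert cls.tolist() == ["tss"]

    def test_tss_precedence_over_tes(self):
        # boundary within radius of g1 TES (60 kb) only -> tes
        cls = classify_vs_genes(bnd([("chr1", 61_000, "+")]), self.GENES)
        assert cls.tolist() == ["tes"]
        # within radius of both g2 TES (85k) and g2 TSS (95k)? no: use a point
        # near g1 TSS and TES is out of range
        both = bnd([("chr1", 58_500, "+")])   # 2.5k of tes=60k? 1500 of tes, 8500 of tss
        assert classify_vs_genes(both, self.GENES).tolist() == ["tes"]

    def test_gene_free_chromosome_neither(self):
        cls = classify_vs_genes(bnd([("chr2", 1000, "+")]), self.GENES)
        assert cls.tolist() == ["neither"]

    def test_partition_exhaustive_and_order_invariant(self):
        rng = np.random.default_rng(1)
        boundaries = bnd([("chr1", int(p), "+")
                          for p in rng.integers(0, 100_000, size=1000)])
        c1 = classify_vs_genes(boundaries, self.GENES)
        c2 = classify_vs_genes(boundaries, list(reversed(self.GENES)))
        assert len(c1) == 1000
        assert set(c1.unique()) <= {"tss", "tes", "neither"}
        assert (c1 == c2).all()


class TestRandomSites:
    def test_empty_template(self, genome):
        out = sample_random_sites(sites_at([], "chr1").iloc[0:0], genome, seed=1)
        assert len(out) == 0

    def test_per_chromosome_counts_match(self, genome):
        template = pd.DataFrame({"chrom": ["chr1"] * 7 + ["chr2"] * 3,
                                 "pos": np.arange(10) * 1000})
        out = sample_random_sites(template, genome, seed=2)
        assert out.groupby("chrom").size().to_dict() == {"chr1": 7, "chr2": 3}

    def test_deterministic_given_seed(self, genome):
        template = pd.DataFrame({"chrom": ["chr1"] * 5, "pos": np.arange(5)})
        a = sample_random_sites(template, genome, seed=3)
        b = sample_random_sites(template, genome, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_match_rate_near_analytic_expectation(self, big_genome):
        # sparse boundaries: P(site within r of a boundary) ~ 2 r n_b / L
        boundaries = bnd([("chr1", int(p), "+")
                          for p in np.arange(20) * 450_000 + 100_000])
        radius, L = 2500, 10_000_000
        expect = 2 * radius * 20 / L
        template = pd.DataFrame({"chrom": ["chr1"] * 50, "pos": np.arange(50)})
        bpos = np.sort(boundaries["pos"].to_numpy())
        rates = []
        for seed in range(100):
            s = sample_random_sites(template, big_genome, seed=seed)
            near = np.abs(s["pos"].to_numpy()[:, None] - bpos[None, :]).min(axis=1)
            rates.append((near <= radius).mean())
        se = np.sqrt(expect * (1 - expect) / (50 * 100))
        assert abs(np.mean(rates) - expect) < 3 * se


class TestEnrichmentTest:
    def test_observed_equal_control_p_near_half(self):
        res = enrichment_test(10_000, 500, 500)
        assert 0.4 < res.p_value < 0.6

    def test_printed_proportions_row1(self):
        res = enrichment_test(4687, 148, 45)
        assert res.pct_obs == 3.15 and res.pct_rand == 0.96

    def test_matches_exact_tail_sum(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(5, 51))
            k_rand = int(rng.integers(1, n))
            k_obs = int(rng.integers(0, n + 1))
            res = enrichment_test(n, k_obs, k_rand)
            assert res.p_value == pytest.approx(
                binom_sf_exact(k_obs, n, k_rand / n), rel=1e-9)

    def test_zero_control_floored_and_flagged(self):
        res = enrichment_test(1000, 5, 0)
        assert res.p0_floored and res.p0 == 0.5 / 1000

    def test_truncation_convention(self):
        assert truncate_pct(148, 4687) == 3.15     # 3.157... truncated
        assert truncate_pct(28, 1148) == 2.43      # 2.439... truncated
        assert truncate_pct(11, 1507) == 0.72
        assert truncate_pct(6, 2032) == 0.29


class TestNearestDistances:
    def test_sites_at_every_boundary_all_zero(self):
        boundaries = bnd([("chr1", p, "+") for p in np.arange(5) * 10_000])
        out = nearest_distance_distribution(boundaries,
                                            sites_at(boundaries["pos"]), "rich", k=5)
        assert out.tolist() == [0] * 5

    def test_k_one_returns_global_minimum(self):
        boundaries = bnd([("chr1", 10_000, "+"), ("chr1", 50_000, "+")])
        out = nearest_distance_distribution(boundaries, sites_at([10_300, 50_050]),
                                            "rich", k=1)
        assert out.tolist() == [50]

    def test_warns_when_fewer_than_k(self):
        boundaries = bnd([("chr1", 10_000, "+")])
        with pytest.warns(UserWarning, match="available"):
            out = nearest_distance_distribution(boundaries, sites_at([10_500]),
                                                "rich", k=10)
        assert out.tolist() == [500]

    def test_rich_side_stochastically_smaller_on_planted_data(self):
        rng = np.random.default_rng(5)
        boundaries = bnd([("chr1", int(p), "+")
                          for p in np.arange(150) * 60_000 + 10_000])
        planted = sites_at(np.concatenate([
            boundaries["pos"] + rng.integers(0, 1500, size=150),      # rich side
            boundaries["pos"] - rng.integers(4000, 20_000, size=150),  # far poor
        ]))
        rich_d = nearest_distance_distribution(boundaries, planted, "rich", k=150)
        poor_d = nearest_distance_distribution(boundaries, planted, "poor", k=150)
        p = stats.mannwhitneyu(rich_d, poor_d, alternative="less").pvalue
        assert p < 0.01


class TestLaminaAlignment:
    def test_empty_lads_rejected(self, big_genome):
        with pytest.raises(ValueError, match="empty"):
            lamina_alignment([], sites_at([1]), CorrelationParams(), big_genome)

    def test_uniform_sites_flat_profile(self, big_genome):
        rng = np.random.default_rng(6)
        lads = [("chr1", int(s), int(s + 200_000))
                for s in np.arange(10) * 1_000_000 + 300_000]
        sites = sites_at(rng.integers(0, 10_000_000, size=60_000))
        params = CorrelationParams(bin_size=2000, span=100_000)
        profile, summary = lamina_alignment(lads, sites, params, big_genome)
        assert np.abs(profile.values - 1.0).max() < 0.25
        assert summary["n_boundaries"] == 20

    def test_interior_planted_sites_elevated_on_poor_side(self, big_genome):
        rng = np.random.default_rng(7)
        lads = [("chr1", int(s), int(s + 300_000))
                for s in np.arange(10) * 1_000_000 + 300_000]
        # sites only in inter-LAD gaps (the lamin-poor interior)
        gaps = [(e, s2) for (_, _, e), (_, s2, _) in zip(lads[:-1], lads[1:])]
        pos = np.concatenate([rng.integers(a, b, size=600) for a, b in gaps])
        params = CorrelationParams(bin_size=2000, span=100_000)
        profile, summary = lamina_alignment(lads, sites_at(pos), params, big_genome)
        poor = profile.values[profile.bin_centers > 0].mean()
        rich = profile.values[profile.bin_centers < 0].mean()
        assert poor > 2 * rich
        assert summary["matched_lamin_poor"] >= summary["matched_lamin_rich"]
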