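"""Correlation engine: normalization fixed point, symmetry, specializations."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import chiptools as ct
from chiptools import (CorrelationParams, correlate, strand_cross_correlation,
                       motif_enrichment_profile, attribute_tags_to_sites,
                       coverage_by_score_class, tss_profile, GenomeTable,
                       GeneRecord, SimulationParams)
from .conftest import make_tags


@pytest.fixture
def flat_genome():
    return GenomeTable((("chr1", 1_000_000),))


class TestCorrelate:
    def test_uniform_target_is_flat_one(self, flat_genome):
        rng = np.random.default_rng(0)
        refs = make_tags([("chr1", int(p), "+")
                          for p in rng.integers(5000, 995_000, size=300)],
                         flat_genome)
        targets = make_tags([("chr1", int(p), "+")
                             for p in rng.integers(0, 1_000_000, size=50_000)],
                            flat_genome)
        prof = correlate(refs, targets, CorrelationParams(bin_size=100, span=2000),
                         flat_genome)
        # Poisson bin expectation: n_ref * bin * density
        expect = 300 * 100 * 50_000 / 1_000_000
        se = 3 * np.sqrt(expect) / expect
        assert np.abs(prof.values - 1.0).max() < se

    def test_single_pair_lands_in_first_positive_bin(self, flat_genome):
        refs = make_tags([("chr1", 1000, "+")], flat_genome)
        targets = make_tags([("chr1", 1010, "+")], flat_genome)
        prof = correlate(refs, targets, CorrelationParams(bin_size=50, span=500),
                         flat_genome)
        nonzero = prof.raw > 0
        assert nonzero.sum() == 1
        assert prof.bin_centers[nonzero][0] == 25.0   # the (0, 50] bin

    def test_zero_distance_goes_positive(self, flat_genome):
        refs = make_tags([("chr1", 1000, "+")], flat_genome)
        targets = make_tags([("chr1", 1000, "+")], flat_genome)
        prof = correlate(refs, targets, CorrelationParams(bin_size=50, span=500),
                         flat_genome)
        assert prof.raw[prof.bin_centers == 25.0][0] == 1

    def test_no_reference_rejected(self, flat_genome):
        empty = make_tags([], flat_genome)
        targets = make_tags([("chr1", 10, "+")], flat_genome)
        with pytest.raises(ValueError, match="reference"):
            correlate(empty, targets, CorrelationParams(), flat_genome)

    def test_ab_equals_ba_mirrored(self, flat_genome):
        # widely spaced references, each with one partner at an odd offset so
        # no distance falls exactly on a (half-open) bin edge
        rng = np.random.default_rng(1)
        apos = 5000 + np.arange(150) * 5000
        delta = 2 * rng.integers(-900, 900, size=150) + 1
        a = make_tags([("chr1", int(p), "+") for p in apos], flat_genome)
        b = make_tags([("chr1", int(p + d), "+")
                       for p, d in zip(apos, delta)], flat_genome)
        params = CorrelationParams(bin_size=100, span=2000)
        ab = correlate(a, b, params, flat_genome)
        ba = correlate(b, a, params, flat_genome)
        # pair at distance d from A's view appears at -d from B's view; with
        # unit counts the normalization factors coincide
        np.testing.assert_allclose(ab.values, ba.values[::-1], atol=1e-9)

    def test_doubling_multiplicities_leaves_profile_unchanged(self, flat_genome):
        rng = np.random.default_rng(2)
        recs = [("chr1", int(p), "+", 2) for p in rng.integers(0, 900_000, size=200)]
        refs = make_tags([("chr1", int(p), "+")
                          for p in rng.integers(3000, 900_000, size=100)], flat_genome)
        params = CorrelationParams(bin_size=100, span=2000, cap=10)
        p1 = correlate(refs, make_tags(recs, flat_genome), params, flat_genome)
        doubled = [(c, p, s, 2 * n) for c, p, s, n in recs]
        p2 = correlate(refs, make_tags(doubled, flat_genome), params, flat_genome)
        np.testing.assert_allclose(p1.values, p2.values, atol=1e-12)


class TestStrandCrossCorrelation:
    def test_fixed_fragment_length_modal_distance(self):
        p = SimulationParams(genome_length=500_000, n_chroms=1, seed=31,
                             n_planted_sites=100, frag_mean=200.0, frag_sd=0.0,
                             frag_min=200, dup_prob=0.0, background_rate=0.0)
        exp = ct.simulate_chip_experiment(p)
        _, modal = strand_cross_correlation(
            exp.tags, CorrelationParams(bin_size=20, span=400))
        assert abs(modal - 200) <= 20

    def test_strand_swap_mirrors_profile(self, flat_genome):
        rng = np.random.default_rng(3)
        recs = []
        for i in range(300):
            p = 2000 + i * 3000   # spaced out: no cross-pair within the span
            recs.append(("chr1", p, "+"))
            # odd separations: no distance sits exactly on a bin edge
            recs.append(("chr1", p + 2 * int(rng.integers(60, 110)) + 1, "-"))
        tags = make_tags(recs, flat_genome)
        swapped = make_tags([(c, p, "+-"[s == "+"], n)
                             for c, p, s, n in tags.frame.itertuples(index=False)],
                            flat_genome)
        params = CorrelationParams(bin_size=50, span=500)
        prof, _ = strand_cross_correlation(tags, params)
        prof_sw, _ = strand_cross_correlation(swapped, params)
        np.testing.assert_allclose(prof.values, prof_sw.values[::-1], atol=1e-9)

    def test_uncorrelated_strands_flat(self, flat_genome):
        rng = np.random.default_rng(4)
        recs = [("chr1", int(p), "+") for p in rng.integers(0, 10**6, size=30_000)]
        recs += [("chr1", int(p), "-") for p in rng.integers(0, 10**6, size=30_000)]
        prof, _ = strand_cross_correlation(make_tags(recs, flat_genome),
                                           CorrelationParams(bin_size=100, span=1000))
        assert np.abs(prof.values - 1.0).max() < 0.15

    def test_empty_strand_rejected(self, flat_genome):
        tags = make_tags([("chr1", 10, "+")], flat_genome)
        with pytest.raises(ValueError, match="strand"):
            strand_cross_correlation(tags, CorrelationParams())


class TestMotifEnrichment:
    def test_sites_at_all_peak_centers(self, flat_genome):
        peaks = pd.DataFrame({"chrom": "chr1", "center": np.arange(21) * 30_000 + 50_000})
        sites = pd.DataFrame({"chrom": "chr1", "center": peaks["center"]})
        res = motif_enrichment_profile(peaks, sites)
        assert res.central_frequency == 1.0
        assert res.encode_pass

    def test_uniform_random_sites_factor_near_one(self, flat_genome):
        rng = np.random.default_rng(5)
        peaks = pd.DataFrame({"chrom": "chr1",
                              "center": rng.integers(20_000, 980_000, size=400)})
        sites = pd.DataFrame({"chrom": "chr1",
                              "center": rng.integers(0, 10**6, size=3000)})
        res = motif_enrichment_profile(peaks, sites)
        p_hit = res.central_frequency
        se = np.sqrt(p_hit * (1 - p_hit) / len(peaks)) / max(p_hit, 1e-9)
        assert abs(res.enrichment_factor - 1.0) <= max(3 * se, 0.35)
        assert not res.encode_pass

    def test_span_smaller_than_window_rejected(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "center": [100]})
        with pytest.raises(ValueError, match="span"):
            motif_enrichment_profile(peaks, peaks, window=300, span=200)


class TestAttribution:
    def make_sites(self, centers):
        return pd.DataFrame({"chrom": "chr1", "pos": np.array(centers) - 7,
                             "center": centers, "strand": "+", "score": 15.0})

    def test_plus_tag_within_range_assigned(self, flat_genome):
        sites = self.make_sites([1000])
        tags = make_tags([("chr1", 850, "+")], flat_genome)  # 150 bp upstream
        out = attribute_tags_to_sites(tags, sites)
        assert out["attributed_tags"].tolist() == [1]

    def test_plus_tag_beyond_range_unassigned(self, flat_genome):
        sites = self.make_sites([1000])
        tags = make_tags([("chr1", 750, "+")], flat_genome)  # 250 bp upstream
        out = attribute_tags_to_sites(tags, sites)
        assert out["attributed_tags"].tolist() == [0]

    def test_minus_tag_goes_to_upstream_site(self, flat_genome):
        sites = self.make_sites([1000, 1300])
        tags = make_tags([("chr1", 1150, "-")], flat_genome)
        out = attribute_tags_to_sites(tags, sites)
        assert out["attributed_tags"].tolist() == [1, 0]

    def test_equidistant_tag_assigned_once_downstream(self, flat_genome):
        sites = self.make_sites([900, 1100])
        tags = make_tags([("chr1", 1000, "+", 3)], flat_genome)
        out = attribute_tags_to_sites(tags, sites)
        # + tags go downstream; multiplicity carried, never double counted
        assert out["attributed_tags"].tolist() == [0, 3]


class TestCoverageByScoreClass:
    def test_equal_means_zero_slope(self):
        sites = pd.DataFrame({"chrom": "chr1", "center": np.arange(100) * 1000,
                              "score": np.repeat([12.5, 14.5, 16.5, 18.5], 25),
                              "attributed_tags": 4})
        fit = coverage_by_score_class(sites)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_exponential_recovered(self):
        scores = np.repeat([12.5, 13.5, 14.5, 15.5, 16.5], 20)
        sites = pd.DataFrame({"chrom": "chr1", "center": np.arange(100) * 1000,
                              "score": scores,
                              "attributed_tags": np.exp(0.7 * scores)})
        fit = coverage_by_score_class(sites)
        assert fit.slope == pytest.approx(0.7, rel=1e-6)
        assert fit.r > 0.99


class TestTssProfile:
    def test_orientation_aware_asymmetry(self, flat_genome):
        genes = [GeneRecord(id="a", chrom="chr1", tss=100_000, tes=150_000, strand="+"),
                 GeneRecord(id="b", chrom="chr1", tss=500_000, tes=450_000, strand="-")]
        # tags strictly downstream of each TSS in transcription direction
        recs = [("chr1", 100_000 + d, "+") for d in range(200, 1800, 25)]
        recs += [("chr1", 500_000 - d, "+") for d in range(200, 1800, 25)]
        tags = make_tags(recs, flat_genome)
        prof = tss_profile(tags, genes, CorrelationParams(bin_size=200, span=2000),
                           flat_genome)
        downstream = prof.values[prof.bin_centers > 0].sum()
        upstream = prof.values[prof.bin_centers < 0].sum()
        assert downstream > 0 and upstream == 0

    def test_empty_gene_set_rejected(self, flat_genome):
        tags = make_tags([("chr1", 10, "+")], flat_genome)
        with pytest.raises(ValueError, match="gene"):
            tss_profile(tags, [], CorrelationParams(), flat_genome)
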