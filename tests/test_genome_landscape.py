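"""Neighbor statistics, metagene profiles, enrichment, and the KS test."""

import numpy as np
import pytest
import scipy.stats

from xdense import genome_landscape as gl
from xdense import synthetic_data as sd
from xdense.genomic_io import Chromosome, GeneModel, Genome, Interval


def mids(*positions, chrom="c"):
    return [Interval(chrom, p, p + 1) for p in positions]


class TestNeighborDistances:
    def test_hand_example_n1(self):
        stats = gl.neighbor_distances(mids(0, 100, 300), n_max=1)["all"]
        assert stats.mean_distance[1] == pytest.approx((100 + 100 + 200) / 3)

    def test_hand_example_n2(self):
        stats = gl.neighbor_distances(mids(0, 100, 300), n_max=2)["all"]
        assert stats.mean_distance[2] == pytest.approx(
            np.mean([(100 + 300) / 2, (100 + 200) / 2, (200 + 300) / 2]))

    def test_isolated_chromosome_peak_excluded(self):
        peaks = mids(0, 100) + mids(500, chrom="c2")
        stats = gl.neighbor_distances(peaks, n_max=1)["all"]
        assert stats.excluded[1] == 1
        assert stats.mean_distance[1] == pytest.approx(100.0)

    def test_mean_distance_nondecreasing_in_n(self, rng):
        peaks = mids(*np.sort(rng.integers(0, 10**6, 50)))
        stats = gl.neighbor_distances(peaks, n_max=4)["all"]
        vals = [stats.mean_distance[n] for n in range(1, 5)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_translation_and_scale_invariance(self, rng):
        pos = np.sort(rng.integers(0, 10**5, 30))
        base = gl.neighbor_distances(mids(*pos), n_max=2)["all"]
        shifted = gl.neighbor_distances(mids(*(pos + 7777)), n_max=2)["all"]
        scaled = gl.neighbor_distances(mids(*(pos * 3)), n_max=2)["all"]
        for n in (1, 2):
            assert shifted.mean_distance[n] == pytest.approx(base.mean_distance[n])
            assert scaled.mean_distance[n] == pytest.approx(3 * base.mean_distance[n])

    def test_small_category_rejected(self):
        with pytest.raises(ValueError):
            gl.neighbor_distances(mids(5), n_max=1)


class TestRandomizeNormalize:
    def test_uniform_peaks_near_one(self):
        g = Genome([Chromosome("chrX", "A" * 1_000_000, "X")])
        rng = np.random.default_rng(23)
        peaks = mids(*np.sort(rng.integers(200, 999_800, 400)), chrom="chrX")
        norm = gl.randomize_and_normalize(peaks, g, n_sets=10, seed=23)["all"]
        for n in range(1, 5):
            assert 0.8 <= norm.mean_distance[n] <= 1.2

    def test_tight_clusters_below_half(self):
        g = Genome([Chromosome("chrX", "A" * 1_000_000, "X")])
        rng = np.random.default_rng(24)
        centers = rng.integers(10_000, 990_000, 12)
        pos = np.concatenate([
            rng.normal(c, 200, 30).astype(int) for c in centers])
        peaks = mids(*np.clip(pos, 0, 999_999), chrom="chrX")
        norm = gl.randomize_and_normalize(peaks, g, n_sets=10, seed=24)["all"]
        assert norm.mean_distance[1] < 0.5

    def test_single_randomized_set_allowed(self):
        g = Genome([Chromosome("c", "A" * 100_000)])
        peaks = mids(100, 5000, 20_000, 70_000)
        norm = gl.randomize_and_normalize(peaks, g, n_sets=1, seed=0)["all"]
        assert np.isfinite(norm.mean_distance[1])

    def test_zero_sets_rejected(self):
        g = Genome([Chromosome("c", "A" * 1000)])
        with pytest.raises(ValueError):
            gl.randomize_and_normalize(mids(1, 2), g, n_sets=0, seed=0)


class TestCesProximity:
    def test_peak_near_ces(self):
        peaks = mids(100, 5000, chrom="chrX")
        ces = [Interval("chrX", 90, 110)]
        labels = gl.classify_ces_proximity(peaks, ces, {"chrX"},
                                           x_median_distance=500)
        assert labels == ["CES", "X_other"]

    def test_autosome_always_autosome(self):
        peaks = mids(100, chrom="chr2") + mids(200, chrom="chrX")
        ces = [Interval("chr2", 90, 110)]
        labels = gl.classify_ces_proximity(peaks, ces, {"chrX"},
                                           x_median_distance=1e9)
        assert labels[0] == "autosome"

    def test_empty_ces_rejected(self):
        with pytest.raises(ValueError):
            gl.classify_ces_proximity(mids(1), [], {"chrX"})


class TestMetagene:
    def test_plus_strand_midgene(self):
        genes = [GeneModel("c", 1000, 2000, "+", "g")]
        prof = gl.metagene_profile(mids(1500), genes, n_bins=60)
        center = (prof.bin_edges[:-1] + prof.bin_edges[1:]) / 2
        assert center[np.argmax(prof.values)] == pytest.approx(0.5, abs=0.05)

    def test_minus_strand_flipped(self):
        genes = [GeneModel("c", 1000, 2000, "-", "g")]
        prof = gl.metagene_profile(mids(1500), genes, n_bins=60)
        center = (prof.bin_edges[:-1] + prof.bin_edges[1:]) / 2
        assert center[np.argmax(prof.values)] == pytest.approx(0.5, abs=0.05)

    def test_upstream_feature_negative_x(self):
        genes = [GeneModel("c", 1000, 2000, "+", "g")]
        prof = gl.metagene_profile(mids(500), genes, n_bins=60)
        center = (prof.bin_edges[:-1] + prof.bin_edges[1:]) / 2
        assert center[np.argmax(prof.values)] == pytest.approx(-0.5, abs=0.05)

    def test_no_features_zero_profile(self):
        genes = [GeneModel("c", 0, 100, "+", "g")]
        prof = gl.metagene_profile([], genes)
        assert np.all(prof.values == 0)

    def test_mass_conservation(self, rng):
        genes = [GeneModel("c", int(s), int(s) + 1000, "+", f"g{i}")
                 for i, s in enumerate(range(0, 50_000, 5000))]
        feats = mids(*rng.integers(0, 50_000, 200))
        prof = gl.metagene_profile(feats, genes, n_bins=60)
        bin_w = 3.0 / 60
        mass = prof.values.sum() * bin_w
        assert mass == pytest.approx(prof.n_incidences / prof.n_genes)


class TestBodyToTssRatio:
    def _uniform_setup(self, seed=29, n_genes=500):
        rng = np.random.default_rng(seed)
        genes, feats = [], []
        for i in range(n_genes):
            start = 30_000 * i + 10_000
            genes.append(GeneModel("c", start, start + 10_000, "+", f"g{i}"))
            lo, hi = start - 500, start + 10_000 + 500
            feats.extend(int(x) for x in rng.integers(lo, hi, 40))
        return genes, mids(*feats)

    def test_uniform_hits_ratio_near_one(self):
        genes, feats = self._uniform_setup()
        ratios = gl.body_to_tss_ratio(feats, genes)
        assert ratios["all"] == pytest.approx(1.0, rel=0.10)

    def test_all_hits_at_tss(self):
        genes = [GeneModel("c", 10_000, 20_000, "+", "g")]
        feats = mids(10_000, 10_001, 10_002)
        ratios = gl.body_to_tss_ratio(feats, genes)
        assert ratios["all"] == 0.0

    def test_no_five_prime_hits_absent(self):
        genes = [GeneModel("c", 10_000, 20_000, "+", "g")]
        feats = mids(15_000)
        assert gl.body_to_tss_ratio(feats, genes)["all"] is None

    def test_strand_symmetry(self):
        plus = [GeneModel("c", 10_000, 20_000, "+", "g")]
        minus = [GeneModel("c", 10_000, 20_000, "-", "g")]
        feats_plus = mids(10_100, 12_000, 15_000)
        feats_minus = mids(19_899, 17_999, 14_999)
        rp = gl.body_to_tss_ratio(feats_plus, plus)["all"]
        rm = gl.body_to_tss_ratio(feats_minus, minus)["all"]
        assert rp == pytest.approx(rm)

    def test_short_gene_rejected(self):
        genes = [GeneModel("c", 0, 200, "+", "g")]
        with pytest.raises(ValueError):
            gl.body_to_tss_ratio([], genes, flank=250)


class TestLocusEnrichment:
    def test_constant_two_fold(self):
        from xdense.genomic_io import CoverageTrack
        chip = CoverageTrack({"c": np.full(100_000, 2.0)})
        inp = CoverageTrack({"c": np.full(100_000, 1.0)})
        loci = [Interval("c", s, s + 1000) for s in range(0, 50_000, 5000)]
        enr = gl.locus_enrichment(chip, inp, loci)
        # library-size normalization cancels the global factor: chip is
        # uniformly 2x input, so normalized enrichment is 1 per locus
        assert np.allclose(enr, 1.0, rtol=0.01)
        enr_raw = gl.locus_enrichment(
            CoverageTrack({"c": np.r_[np.full(1000, 2.0), np.ones(99_000)]}),
            inp, [Interval("c", 0, 1000)])
        assert enr_raw[0] > 1.5

    def test_zero_input_finite(self):
        from xdense.genomic_io import CoverageTrack
        chip = CoverageTrack({"c": np.full(1000, 5.0)})
        inp = CoverageTrack({"c": np.r_[np.zeros(100), np.ones(900)]})
        (e,) = gl.locus_enrichment(chip, inp, [Interval("c", 0, 100)])
        assert np.isfinite(e) and e > 1

    def test_planted_enrichment_ordering_by_repeat_length(self):
        """Longer planted GA runs get higher planted ChIP enrichment."""
        specs = [sd.ChromSpec("chr2", 300_000, "autosome")]
        genome, _ = sd.generate_genome(specs, seed=31)
        long_loci = [Interval("chr2", 2000 * i + 500, 2000 * i + 520)
                     for i in range(50)]
        short_loci = [Interval("chr2", 2000 * i + 1500, 2000 * i + 1504)
                      for i in range(50)]
        chip, inp, _ = sd.generate_coverage(
            genome, long_loci + short_loci,
            [5.0] * 50 + [1.0] * 50, seed=31, base_rate=2.0)
        e_long = gl.locus_enrichment(chip, inp, long_loci)
        e_short = gl.locus_enrichment(chip, inp, short_loci)
        assert np.median(e_long) > np.median(e_short)

    def test_mismatched_tracks_rejected(self):
        from xdense.genomic_io import CoverageTrack
        with pytest.raises(ValueError):
            gl.locus_enrichment(CoverageTrack({"a": np.ones(10)}),
                                CoverageTrack({"b": np.ones(10)}), [])


class TestKsTwoSample:
    def test_identical_samples(self):
        x = np.arange(30.0)
        d, p = gl.ks_two_sample(x, x)
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self, rng):
        a = rng.uniform(0, 1, 100)
        b = rng.uniform(2, 3, 100)
        d, p = gl.ks_two_sample(a, b)
        assert d == 1.0 and p < 1e-10

    def test_matches_scipy(self, rng):
        a = rng.normal(size=200)
        b = rng.normal(0.3, 1.0, size=150)
        d, p = gl.ks_two_sample(a, b)
        ref = scipy.stats.ks_2samp(a, b)
        assert d == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=0.1)

    def test_exact_small_sample_matches_scipy(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=15)
        d, p = gl.ks_two_sample(a, b)
        ref = scipy.stats.ks_2samp(a, b, method="exact")
        assert p == pytest.approx(ref.pvalue)

    def test_invariant_under_monotone_transform(self, rng):
        a = rng.uniform(0.1, 5, 80)
        b = rng.uniform(0.1, 5, 90)
        d1, _ = gl.ks_two_sample(a, b)
        d2, _ = gl.ks_two_sample(np.log(a), np.log(b))
        assert d1 == pytest.approx(d2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            gl.ks_two_sample([], [1.0])
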