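"""Probe classification, mixture fitting, repeat-length intensity, flank scan."""

import numpy as np
import pytest

from xdense import motif_model as mm
from xdense import pbm_analysis as pa
from xdense import synthetic_data as sd
from xdense.genomic_io import Interval, ProbeRecord


def probe(med, seq="A" * 36, pid="p"):
    return ProbeRecord(pid, seq, [float(med)])


class TestClassifyPbm:
    def test_strictly_above_is_positive(self):
        assert pa.classify_pbm([probe(6501)]) == ["PBM+"]

    def test_boundary_is_negative(self):
        assert pa.classify_pbm([probe(6500)]) == ["PBM-"]

    def test_zero_intensity(self):
        assert pa.classify_pbm([probe(0)]) == ["PBM-"]


class TestBimodalThreshold:
    def test_planted_mixture_threshold_separates(self):
        rng = np.random.default_rng(7)
        logx = np.concatenate([rng.normal(8, 0.5, 1000), rng.normal(11, 0.5, 1000)])
        thr = pa.find_bimodal_threshold(2.0 ** logx)
        # any threshold separating the planted components with < 5%
        # misassignment is acceptable
        mis = np.mean(2.0 ** logx[:1000] > thr) + np.mean(2.0 ** logx[1000:] <= thr)
        assert mis / 2 < 0.05
        assert 2 ** 9 < thr < 2 ** 10

    def test_single_gaussian_fails(self):
        rng = np.random.default_rng(1)
        with pytest.raises(pa.NoBimodalityError):
            pa.find_bimodal_threshold(2.0 ** rng.normal(10, 0.5, 500))

    def test_two_tight_clusters(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(100, 1, 100), rng.normal(10000, 50, 100)])
        thr = pa.find_bimodal_threshold(x)
        assert 110 < thr < 9800


class TestClassifyMre:
    def test_three_way_labels(self):
        pwm = mm.build_pwm(["GAGAGAGAGA"], pseudocount=0.01)
        consensus_seq = "T" * 10 + "GAGAGAGAGA" + "T" * 10
        random_seq = "TGCATGCATCGATTACGCGAT"
        labels = pa.classify_mre([consensus_seq, random_seq], pwm)
        assert labels[0] == "MRE+"
        assert labels[1] == "MRE-"

    def test_ambiguous_gap(self):
        pwm = mm.build_pwm(["GAGAGAGAGA"], pseudocount=0.01)
        scorer = mm.PWMScorer(pwm)
        # find a sequence whose best p lands inside (1e-4, 1e-3]
        rng = np.random.default_rng(3)
        for _ in range(3000):
            seq = "".join(rng.choice(list("ACGT"), 30))
            p = mm.best_hit_p_value(pwm, seq, scorer=scorer)
            if 1e-4 <= p <= 1e-3:
                assert pa.classify_mre([seq], pwm) == ["ambiguous"]
                return
        pytest.skip("no gap sequence found")


class TestMixture:
    def test_planted_recovery(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(8, 0.5, 3000), rng.normal(11, 0.5, 2000)])
        fit = pa.fit_two_gaussian_mixture(x, seed=11)
        assert fit.converged
        assert np.allclose(fit.means, [8, 11], atol=0.1)
        assert np.allclose(fit.weights, [0.6, 0.4], atol=0.03)

    def test_identical_observations_rejected(self):
        with pytest.raises(ValueError):
            pa.fit_two_gaussian_mixture([5.0] * 100, seed=0)

    def test_strong_set_above_crossing(self):
        rng = np.random.default_rng(12)
        x = np.concatenate([rng.normal(8, 0.5, 2000), rng.normal(11, 0.5, 2000)])
        fit = pa.fit_two_gaussian_mixture(x, seed=0)
        # posterior is monotone in x for equal-ish sds: the strong set must sit
        # entirely above the 0.5 crossing point
        crossing = x[np.argmin(np.abs(fit.posteriors - 0.5))]
        assert np.all(x[fit.strong_set] > crossing)

    def test_agreement_with_kde_threshold(self):
        """Mixture split and KDE valley split agree on well-separated data."""
        rng = np.random.default_rng(13)
        logx = np.concatenate([rng.normal(8, 0.5, 2000), rng.normal(11, 0.5, 2000)])
        thr = pa.find_bimodal_threshold(2.0 ** logx)
        fit = pa.fit_two_gaussian_mixture(logx, seed=0)
        kde_labels = 2.0 ** logx > thr
        em_labels = fit.posteriors > 0.5
        assert np.mean(kde_labels == em_labels) > 0.95


class TestQuantiles:
    def test_top_quantile_is_q1(self):
        probes = [probe(i, pid=str(i)) for i in range(1, 11)]
        labels = pa.quantile_split(probes, k=5)
        assert [l for p, l in zip(probes, labels) if p.median_intensity >= 9] == ["q1", "q1"]
        assert [l for p, l in zip(probes, labels) if p.median_intensity <= 2] == ["q5", "q5"]

    def test_balanced_sizes(self):
        probes = [probe(i, pid=str(i)) for i in range(13)]
        labels = pa.quantile_split(probes, k=5)
        sizes = [labels.count(f"q{i}") for i in range(1, 6)]
        assert max(sizes) - min(sizes) <= 1

    def test_ties_deterministic_by_input_order(self):
        probes = [probe(5, pid=str(i)) for i in range(4)]
        assert pa.quantile_split(probes, k=2) == ["q1", "q1", "q2", "q2"]

    def test_k_equals_n(self):
        probes = [probe(i, pid=str(i)) for i in range(5)]
        assert sorted(pa.quantile_split(probes, k=5)) == [f"q{i}" for i in range(1, 6)]

    def test_too_few_probes(self):
        with pytest.raises(ValueError):
            pa.quantile_split([probe(1)], k=2)


class TestIntensityByRepeatLength:
    def test_run_assignment_and_cap(self):
        p4 = probe(100, seq="T" * 14 + "GA" * 4 + "T" * 14)
        p13 = probe(100, seq="T" * 5 + "GA" * 13 + "T" * 5)
        table = pa.intensity_by_repeat_length([p4, p13])
        assert set(table.repeat_units) == {"4", ">=11"}

    def test_planted_monotone_plateau(self):
        probes, truth = sd.generate_repeat_probe_set(
            run_lengths=range(1, 14), seed=3, n_per_length=30)
        table = pa.intensity_by_repeat_length(probes)
        meds = table.set_index("units_numeric")["median"]
        rising = meds.loc[1:10]
        assert (rising.diff().dropna() > -50).all()  # non-decreasing up to noise
        assert rising.iloc[-1] - rising.iloc[0] > 5 * 400  # strong planted slope
        # plateau: capped bins stay near the 10-unit level
        assert abs(meds.loc[11] - meds.loc[10]) < 150


class TestFlankScan:
    def test_planted_four_three_window(self, probe_set):
        probes, truth = probe_set
        core = mm.build_pwm([truth["config"].core], pseudocount=0.01)
        bound = [p.variable_seq for p in probes if p.chip_flag == "+"]
        unbound = [p.variable_seq for p in probes if p.chip_flag == "-"]
        res = pa.flank_separation_scan(bound, unbound, core)
        assert res.minimal_window == truth["minimal_window"] == (4, 3)
        assert res.total_motif_length == truth["total_motif_length"] == 15
        # brute-force set-intersection oracle at a few cells
        aln_b = mm.align_to_pwm(bound, core)
        aln_u = mm.align_to_pwm(unbound, core)
        for a, b in [(0, 0), (4, 3), (2, 1)]:
            kb = {x.oriented_seq[x.core_start - a : x.core_start + 8 + b]
                  for x in aln_b}
            ku = {x.oriented_seq[x.core_start - a : x.core_start + 8 + b]
                  for x in aln_u}
            assert res.overlap_matrix[a, b] == pytest.approx(
                100 * len(kb & ku) / len(kb))

    def test_overlap_matrix_monotone(self, probe_set):
        probes, truth = probe_set
        core = mm.build_pwm([truth["config"].core], pseudocount=0.01)
        bound = [p.variable_seq for p in probes if p.chip_flag == "+"]
        unbound = [p.variable_seq for p in probes if p.chip_flag == "-"]
        res = pa.flank_separation_scan(bound, unbound, core, mode="token")
        M = res.overlap_matrix
        assert np.all(np.diff(M, axis=0) <= 1e-9)
        assert np.all(np.diff(M, axis=1) <= 1e-9)

    def test_identical_sets_full_overlap(self, probe_set):
        probes, truth = probe_set
        core = mm.build_pwm([truth["config"].core], pseudocount=0.01)
        bound = [p.variable_seq for p in probes if p.chip_flag == "+"][:50]
        res = pa.flank_separation_scan(bound, bound, core, max5=3, max3=3)
        assert np.allclose(res.overlap_matrix, 100.0)
        assert res.minimal_window is None and res.total_motif_length is None

    def test_disjoint_cores_separate_immediately(self, rng):
        core = mm.build_pwm(["GAGAGAGA"], pseudocount=0.01)
        bound = ["T" * 10 + "GAGAGAGA" + "T" * 10 for _ in range(5)]
        # A/C alphabet cannot contain the GA-core on either strand
        unbound = ["".join(rng.choice(list("AC"), 28)) for _ in range(5)]
        res = pa.flank_separation_scan(bound, unbound, core, max5=2, max3=2)
        assert res.overlap_matrix[0, 0] == 0.0
        assert res.minimal_window == (0, 0)
        assert res.total_motif_length == 8

    def test_empty_sets_rejected(self):
        core = mm.build_pwm(["GAGAGAGA"])
        with pytest.raises(ValueError):
            pa.flank_separation_scan([], ["A" * 20], core)


class TestOccupancyByMotifClass:
    def test_planted_three_fold_enrichment(self):
        from xdense.genome_landscape import ks_two_sample

        rng = np.random.default_rng(9)
        core, full5, full3 = "GAGAGAGA", "TACT", "CGT"
        seq = list("".join(rng.choice(list("CT"), 400_000)))
        full_sites, core_sites = [], []
        for i in range(200):
            pos = 1000 * i + 100
            seq[pos : pos + 15] = full5 + core + full3
            full_sites.append(pos)
        for i in range(200):
            pos = 1000 * i + 600
            seq[pos : pos + 8] = core
            core_sites.append(pos)
        from xdense.genomic_io import Chromosome, Genome
        genome = Genome([Chromosome("chr2", "".join(seq), "autosome")])
        loci = [Interval("chr2", p, p + 15) for p in full_sites]
        chip, inp, _ = sd.generate_coverage(genome, loci, [3.0] * len(loci), seed=9)
        core_pwm = mm.build_pwm([core], pseudocount=0.01)
        full_pwm = mm.build_pwm([full5 + core + full3], pseudocount=0.01)
        enr = pa.occupancy_by_motif_class(genome, core_pwm, full_pwm, chip, inp)
        med_m = np.median(enr["matched_flank"])
        med_u = np.median(enr["unmatched_flank"])
        assert med_m > med_u
        d, p = ks_two_sample(enr["matched_flank"], enr["unmatched_flank"])
        assert p < 0.01

    def test_zero_core_hits_rejected(self):
        from xdense.genomic_io import Chromosome, Genome
        genome = Genome([Chromosome("chr2", "T" * 1000, "autosome")])
        core_pwm = mm.build_pwm(["GAGAGAGA"], pseudocount=0.01)
        with pytest.raises(ValueError):
            pa.occupancy_by_motif_class(genome, core_pwm, core_pwm, None, None)
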