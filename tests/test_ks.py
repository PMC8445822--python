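import math
import warnings

import numpy as np
import pytest

from paleosyn.ks import (
    fit_ks_peaks,
    ks_density,
    nei_gojobori_ks,
    rate_correct,
)
from paleosyn.model import ValidationError
from paleosyn.simulate import evolve_cds


class TestNeiGojobori:
    def test_identical_sequences(self):
        est = nei_gojobori_ks("ATGGCTGGT", "ATGGCTGGT")
        assert est.Sd == 0 and est.Nd == 0
        assert est.ks == 0
        assert est.valid

    def test_hand_counted_synonymous_change(self):
        # TTT(Phe) has 1/3 synonymous site, GGG(Gly) has 1; the single
        # third-position change TTT->TTC is synonymous on every pathway:
        # S = (1/3 + 1 + 1), Sd = 1, pS = 3/7, dS = -(3/4) ln(3/7)
        est = nei_gojobori_ks("TTTGGGGGG", "TTCGGGGGG")
        assert est.S == pytest.approx(7 / 3)
        assert est.Sd == pytest.approx(1.0)
        assert est.Nd == pytest.approx(0.0)
        assert est.ks == pytest.approx(-0.75 * math.log(3 / 7))

    def test_saturation_flags_invalid(self):
        # every codon differs by a synonymous third-position change: pS = 1
        a, b = "GGT" * 10, "GGC" * 10
        est = nei_gojobori_ks(a, b)
        assert est.ps >= 0.75
        assert not est.valid
        assert math.isnan(est.ks)

    def test_symmetry_is_exact(self):
        pairs = evolve_cds({("x", "y"): 0.4, ("u", "v"): 1.2}, codon_length=150, seed=9)
        for p in pairs:
            fwd = nei_gojobori_ks(p.seq_a, p.seq_b)
            rev = nei_gojobori_ks(p.seq_b, p.seq_a)
            assert (fwd.S, fwd.N, fwd.Sd, fwd.Nd, fwd.ks) == (
                rev.S,
                rev.N,
                rev.Sd,
                rev.Nd,
                rev.ks,
            )

    def test_small_divergence_limit(self):
        # 1 synonymous change over 100 one-synonymous-site codons: pS = 0.01
        a = "GGT" * 100
        b = "GGC" + "GGT" * 99
        est = nei_gojobori_ks(a, b)
        assert est.ps == pytest.approx(0.01)
        assert est.ks == pytest.approx(0.01, rel=0.01)

    def test_matches_biopython_ng86(self):
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        pairs = evolve_cds(
            {("a", "b"): 0.2, ("c", "d"): 0.7, ("e", "f"): 1.5}, codon_length=300, seed=4
        )
        for p in pairs:
            mine = nei_gojobori_ks(p.seq_a, p.seq_b)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dn, ds = cal_dn_ds(CodonSeq(p.seq_a), CodonSeq(p.seq_b), method="NG86")
            assert mine.ks == pytest.approx(ds, abs=1e-9)
            assert mine.kn == pytest.approx(dn, abs=1e-9)

    def test_gap_columns_dropped_pairwise(self):
        est = nei_gojobori_ks("TTTGGG---", "TTCGGGAAA")
        assert est.n_codons == 2

    @pytest.mark.parametrize(
        "a,b,message",
        [
            ("ATGGCT", "ATGGCTAAA", "length mismatch"),
            ("ATGG", "ATGC", "not divisible"),
            ("TAAGGG", "TATGGG", "stop"),
        ],
    )
    def test_validation_errors(self, a, b, message):
        with pytest.raises(ValidationError, match=message):
            nei_gojobori_ks(a, b)


class TestKsDensity:
    def test_point_mass_peaks_at_value(self):
        dens = ks_density([0.5] * 100, bandwidth=0.05, ks_max=3.0)
        assert abs(dens.grid[np.argmax(dens.density)] - 0.5) < 0.01

    def test_single_value_integrates_to_one(self):
        dens = ks_density([1.0], bandwidth=0.05, ks_max=3.0)
        assert np.trapezoid(dens.density, dens.grid) == pytest.approx(1.0, abs=0.01)

    def test_argmax_recovers_normal_mode(self):
        rng = np.random.default_rng(12)
        vals = np.abs(rng.normal(0.3, 0.05, 2000))
        dens = ks_density(vals, bandwidth=0.05, ks_max=3.0)
        assert abs(dens.grid[np.argmax(dens.density)] - 0.3) < 0.02

    def test_values_above_ks_max_excluded_and_counted(self):
        dens = ks_density([0.5, 0.6, 5.0, 7.0], ks_max=3.0)
        assert dens.n_retained == 2 and dens.n_total == 4
        assert np.trapezoid(dens.density, dens.grid) == pytest.approx(0.5, abs=0.01)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            ks_density([])


class TestFitKsPeaks:
    def test_single_component(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0.5, 0.08, 3000)
        model = fit_ks_peaks(ks_density(vals))
        assert model.n_components == 1
        assert model.adequate
        assert abs(model.means[0] - 0.5) < 0.02

    def test_two_components_match_em_oracle(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(6)
        vals = np.concatenate([rng.normal(0.2, 0.05, 2000), rng.normal(1.0, 0.08, 2000)])
        vals = vals[vals >= 0]
        model = fit_ks_peaks(ks_density(vals))
        assert model.n_components == 2
        em = GaussianMixture(n_components=2, random_state=0).fit(vals.reshape(-1, 1))
        em_means = sorted(em.means_.ravel())
        for mine, ref in zip(model.means, em_means):
            assert abs(mine - ref) < 0.03

    def test_well_separated_three_component_recovery(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate(
            [
                rng.normal(0.15, 0.05, 2000),
                rng.normal(0.55, 0.05, 2000),
                rng.normal(1.0, 0.05, 2000),
            ]
        ).clip(0)
        model = fit_ks_peaks(ks_density(vals))
        assert model.n_components == 3
        for mine, truth in zip(model.means, (0.15, 0.55, 1.0)):
            assert abs(mine - truth) < 0.05

    def test_parameter_recovery_across_replicates(self):
        # separation >= 3 bandwidths, n >= 2000: means within 0.05 in >= 90%
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            truth = (0.3, 0.9)
            vals = np.concatenate(
                [rng.normal(truth[0], 0.06, 1200), rng.normal(truth[1], 0.09, 1200)]
            ).clip(0)
            model = fit_ks_peaks(ks_density(vals))
            if model.n_components == 2 and all(
                abs(m - t) < 0.05 for m, t in zip(model.means, truth)
            ):
                ok += 1
        assert ok >= 9


class TestRateCorrect:
    def test_identity_when_modes_equal(self):
        out = rate_correct({"x": [0.3, 0.9], "y": [0.5]}, {"x": 1.2, "y": 1.2})
        assert out["x"].scale == pytest.approx(1.0)
        assert out["x"].corrected_means == pytest.approx((0.3, 0.9))

    def test_double_rate_halves_peaks(self):
        out = rate_correct({"slow": [0.4], "fast": [0.8]}, {"slow": 1.0, "fast": 2.0})
        target = math.sqrt(2.0)
        assert out["fast"].scale == pytest.approx(target / 2.0)
        assert out["fast"].corrected_means[0] == pytest.approx(0.8 * target / 2.0)
        # shared divergence aligns after correction
        assert out["fast"].corrected_means[0] == pytest.approx(
            out["slow"].corrected_means[0] * 2 / 2, rel=1e-9
        )

    def test_fast_lineage_realigns_shared_peak(self):
        # lineage rate x1.5 inflates both its WGD peak and its reference mode
        rate = 1.5
        shared_peak, ref_mode = 0.6, 1.0
        out = rate_correct(
            {"normal": [shared_peak], "fast": [shared_peak * rate]},
            {"normal": ref_mode, "fast": ref_mode * rate},
        )
        gap_before = abs(shared_peak * rate - shared_peak)
        gap_after = abs(
            out["fast"].corrected_means[0] - out["normal"].corrected_means[0]
        )
        assert gap_before > 0.25
        assert gap_after < 0.05

    def test_ordering_preserved(self):
        out = rate_correct({"x": [0.2, 0.7, 1.4]}, {"x": 0.5})
        assert list(out["x"].corrected_means) == sorted(out["x"].corrected_means)

    def test_non_positive_mode_rejected(self):
        with pytest.raises(ValidationError):
            rate_correct({"x": [0.3]}, {"x": 0.0})


class TestPipelineRecovery:
    def test_wgd_cohort_peak_recovered_from_sequences(self):
        """True Ks of one WGD cohort -> CDS -> estimator -> density -> peak."""
        from paleosyn.simulate import EvolutionScenario, Wgd, simulate_genomes

        scenario = EvolutionScenario(
            tree="(A:0.9,B:0.9);",
            n_chromosomes=4,
            genes_per_chromosome=120,
            events={"B": [Wgd(retention=0.9, time_fraction=0.5)]},
            ks_noise_sd=0.0,
            seed=21,
        )
        result = simulate_genomes(scenario)
        paralog_pairs = {
            pair: ks
            for pair, ks in result.truth.pair_ks.items()
            if pair[0].startswith("B") and pair[1].startswith("B")
        }
        true_peak = 0.9  # duplication at mid-branch: 2 * 0.45
        assert np.allclose(list(paralog_pairs.values()), true_peak)
        cds = evolve_cds(paralog_pairs, codon_length=600, seed=22)
        estimates = [nei_gojobori_ks(p.seq_a, p.seq_b) for p in cds]
        ks_vals = [e.ks for e in estimates if e.valid]
        assert np.mean(ks_vals) == pytest.approx(true_peak, abs=0.05)
        model = fit_ks_peaks(ks_density(ks_vals))
        assert model.n_components == 1
        assert abs(model.means[0] - true_peak) < 0.05
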