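"""Synthetic-cohort generator: ground-truth sampling, signal model, IO."""

import numpy as np
import pytest
from scipy import stats as sstats

from ictonet.synth import (GroundTruthSpec, band_power_fraction, generate_cohort,
                           generate_ground_truth, load_cohort, save_cohort,
                           simulate_recording)


class TestGroundTruth:
    def test_empty_graph_at_zero_density(self):
        spec = GroundTruthSpec(n_regions=10, duration=1.0, base_density=0.0)
        w = generate_ground_truth(spec, "control", 1)
        assert np.all(w == 0)

    def test_complete_graph_at_full_density(self):
        spec = GroundTruthSpec(n_regions=10, duration=1.0, base_density=1.0,
                               base_strength=0.37)
        w = generate_ground_truth(spec, "control", 1)
        off = w[~np.eye(10, dtype=bool)]
        assert np.all(off == 0.37)
        assert np.all(np.diag(w) == 0)

    def test_symmetry_and_nonnegativity(self):
        spec = GroundTruthSpec(n_regions=30, duration=1.0, base_density=0.3)
        w = generate_ground_truth(spec, "patient", 7)
        assert np.array_equal(w, w.T)
        assert np.all(w >= 0)

    def test_realized_density_matches_binomial_sampling(self):
        # mean density over many draws within 3 standard errors of p
        p = 0.2
        spec = GroundTruthSpec(n_regions=90, duration=1.0, base_density=p)
        n_pairs = 90 * 89 // 2
        n_draws = 1000
        dens = np.empty(n_draws)
        for s in range(n_draws):
            w = generate_ground_truth(spec, "control", s)
            dens[s] = (w[np.triu_indices(90, 1)] > 0).mean()
        se = np.sqrt(p * (1 - p) / (n_pairs * n_draws))
        assert abs(dens.mean() - p) < 3 * se

    def test_patient_density_scaled_and_capped(self):
        spec = GroundTruthSpec(n_regions=40, duration=1.0, base_density=0.8,
                               patient_effect=2.0)
        with pytest.warns(RuntimeWarning, match="capping"):
            w = generate_ground_truth(spec, "patient", 3)
        assert (w[np.triu_indices(40, 1)] > 0).all()  # capped at density 1

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            GroundTruthSpec(n_regions=1, duration=1.0)


class TestRecording:
    def test_independent_channels_have_null_envelope_correlation(self):
        spec = GroundTruthSpec(n_regions=4, duration=30.0, base_density=0.0,
                               leakage_strength=0.0, sensor_noise=0.0)
        _, state = simulate_recording(np.zeros((4, 4)), spec, "control", "s",
                                      11, return_state=True)
        env = state["envelopes"]
        r = np.corrcoef(env)
        off = r[~np.eye(4, dtype=bool)]
        # null band for ~18000-sample correlated-OU series (effective n is
        # duration/timescale ~ 100 independent draws): |r| well below 0.5
        assert np.all(np.abs(off) < 0.5)
        assert np.median(np.abs(off)) < 0.25

    def test_envelope_correlation_tracks_ground_truth(self):
        # oracle: direct correlation of the generated envelope paths
        rho = 0.8
        spec = GroundTruthSpec(n_regions=2, duration=30.0, base_density=1.0,
                               base_strength=rho, leakage_strength=0.0,
                               sensor_noise=0.0)
        truth = np.array([[0.0, rho], [rho, 0.0]])
        direct = []
        for s in range(60):
            _, state = simulate_recording(truth, spec, "control", "s", s,
                                          return_state=True)
            env = state["envelopes"]
            direct.append(np.corrcoef(env)[0, 1])
        direct = np.asarray(direct)
        # log-normal transform of the correlated OU drivers slightly shrinks
        # the correlation: (e^{s^2 rho}-1)/(e^{s^2}-1) with s = 0.5
        s2 = spec.log_amp_sigma**2
        expected = (np.exp(s2 * rho) - 1) / (np.exp(s2) - 1)
        ci = 3 * direct.std(ddof=1) / np.sqrt(len(direct))
        assert abs(direct.mean() - expected) < max(ci, 0.03)

    def test_leakage_induces_zero_lag_signal_correlation(self):
        spec = GroundTruthSpec(n_regions=2, duration=30.0, base_density=0.0,
                               leakage_strength=0.5, sensor_noise=0.1)
        corrs = [
            np.corrcoef(simulate_recording(np.zeros((2, 2)), spec, "control",
                                           "s", s).data)[0, 1]
            for s in range(20)
        ]
        # mixing m = i + eps*b correlates otherwise independent channels
        assert np.mean(np.abs(corrs)) > 0.05

    def test_signal_power_concentrates_in_band(self):
        spec = GroundTruthSpec(n_regions=6, duration=30.0, base_density=0.2,
                               sensor_noise=0.0, leakage_strength=0.0)
        truth = generate_ground_truth(spec, "control", 2)
        rec = simulate_recording(truth, spec, "control", "s", 2)
        assert band_power_fraction(rec.data, rec.fs, spec.band) >= 0.8

    def test_unstable_ou_timescale_rejected(self):
        with pytest.raises(ValueError):
            GroundTruthSpec(n_regions=4, duration=1.0, envelope_timescale=0.0)

    def test_dimension_mismatch_rejected(self):
        spec = GroundTruthSpec(n_regions=4, duration=1.0)
        with pytest.raises(ValueError):
            simulate_recording(np.zeros((3, 3)), spec, "control", "s", 0)


class TestCohort:
    def test_cohort_generation_is_deterministic(self):
        spec = GroundTruthSpec(n_regions=4, duration=5.0, base_density=0.3)
        recs1, truths1 = generate_cohort(spec, 2, 2, master_seed=42)
        recs2, truths2 = generate_cohort(spec, 2, 2, master_seed=42)
        for a, b in zip(recs1, recs2):
            assert a.subject_id == b.subject_id
            assert np.array_equal(a.data, b.data)
            assert a.covariates == b.covariates
        for sid in truths1:
            assert np.array_equal(truths1[sid], truths2[sid])

    def test_single_control_shape_contract(self):
        spec = GroundTruthSpec(n_regions=5, duration=10.0)
        recs, _ = generate_cohort(spec, 1, 0, master_seed=1)
        assert len(recs) == 1
        assert recs[0].group == "control"
        assert recs[0].data.shape == (5, int(10.0 * spec.fs))

    def test_null_patient_effect_gives_indistinguishable_densities(self):
        spec = GroundTruthSpec(n_regions=20, duration=1.0, base_density=0.3,
                               patient_effect=1.0)
        iu = np.triu_indices(20, 1)
        ctl = [(generate_ground_truth(spec, "control", s)[iu] > 0).mean()
               for s in range(200)]
        pat = [(generate_ground_truth(spec, "patient", 1000 + s)[iu] > 0).mean()
               for s in range(200)]
        _, p = sstats.mannwhitneyu(ctl, pat, alternative="two-sided")
        assert p > 0.01

    def test_patient_covariates_present(self):
        spec = GroundTruthSpec(n_regions=4, duration=5.0)
        recs, _ = generate_cohort(spec, 1, 1, master_seed=3)
        pat = [r for r in recs if r.group == "patient"][0]
        assert "epilepsy_duration_years" in pat.covariates
        assert 17.0 <= pat.covariates["age_years"] <= 47.0

    def test_save_load_roundtrip(self, tmp_path):
        spec = GroundTruthSpec(n_regions=4, duration=5.0, base_density=0.5)
        recs, truths = generate_cohort(spec, 1, 1, master_seed=9)
        save_cohort(recs, truths, tmp_path / "cohort")
        loaded = load_cohort(tmp_path / "cohort")
        assert [r.subject_id for r in loaded] == [r.subject_id for r in recs]
        for a, b in zip(recs, loaded):
            assert np.array_equal(a.data, b.data)
            assert a.fs == b.fs
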