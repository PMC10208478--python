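"""Synthetic-data generator: schedules, dynamics, pupil, BOLD, cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import solve_discrete_lyapunov

from pupilec.synthetic_data import (InfeasibleScheduleError, ParadigmSpec,
                                    default_ground_truth,
                                    generate_cohort, generate_event_schedule,
                                    pupil_kernel, recovery_ground_truth,
                                    simulate_bold_rois, simulate_latent_eeg,
                                    simulate_pupil, validate_event_schedule)
from pupilec.pupillometry import compute_tepr, epoch_pupil


class TestEventSchedule:
    def test_study_design_counts_and_gaps(self):
        spec = ParadigmSpec(rng_seed=7)          # 105 trials, 20% oddball
        ev = generate_event_schedule(spec)
        types = ev["trial_type"].to_numpy()
        assert (types == "oddball").sum() == 21
        assert (types == "standard").sum() == 84
        gaps = np.diff(ev["onset"].to_numpy())
        assert gaps.min() >= 2.2 and gaps.max() <= 3.2

    def test_infeasible_schedule_raises(self):
        with pytest.raises(InfeasibleScheduleError, match="infeasible"):
            generate_event_schedule(ParadigmSpec(n_trials_per_run=5))

    def test_validator_clean_over_many_seeds(self):
        spec = ParadigmSpec()
        for seed in range(150):
            ev = generate_event_schedule(
                spec, rng=np.random.default_rng(seed))
            assert validate_event_schedule(ev, spec) == []

    def test_validator_catches_violations(self):
        spec = ParadigmSpec(rng_seed=1)
        ev = generate_event_schedule(spec)
        bad = ev.copy()
        bad.loc[0, "trial_type"] = "oddball"
        msgs = validate_event_schedule(bad, spec)
        assert any("first" in m for m in msgs)

    def test_deterministic_given_seed(self):
        a = generate_event_schedule(ParadigmSpec(rng_seed=11))
        b = generate_event_schedule(ParadigmSpec(rng_seed=11))
        pd.testing.assert_frame_equal(a, b)


class TestLatentDynamics:
    def _truth(self, **kw):
        base = dict(n_nodes=2, A_true=np.zeros((2, 2)),
                    B_true=np.zeros((2, 2, 2)), D_true=np.zeros(2),
                    leadfield_L=np.eye(2), indicator_G=np.eye(2),
                    state_noise_prec=np.inf, obs_noise_prec=np.inf,
                    source_noise_prec=np.inf)
        base.update(kw)
        from pupilec.synthetic_data import GroundTruthModel
        return GroundTruthModel(**base)

    def _no_events(self):
        return pd.DataFrame({"onset": [], "duration": [], "trial_type": [],
                             "response_time": []})

    def test_null_system_is_identically_zero(self):
        truth = self._truth()
        states, eeg, _ = simulate_latent_eeg(truth, self._no_events(), 5.0)
        assert not states.any() and not eeg.any()

    def test_ar1_autocorrelation_matches_closed_form(self):
        truth = self._truth(A_true=0.5 * np.eye(2), state_noise_prec=1.0)
        rng = np.random.default_rng(0)
        states, _, _ = simulate_latent_eeg(truth, self._no_events(),
                                           100.0, rng=rng)
        for i in range(2):
            x = states[:, i]
            rho = np.corrcoef(x[:-1], x[1:])[0, 1]
            assert rho == pytest.approx(0.5, abs=0.03)

    def test_stationary_variance_matches_lyapunov(self):
        A = np.diag([0.6, 0.3])
        truth = self._truth(A_true=A, state_noise_prec=1.0)
        rng = np.random.default_rng(1)
        states, _, _ = simulate_latent_eeg(truth, self._no_events(),
                                           200.0, rng=rng)
        Sigma = solve_discrete_lyapunov(A, np.eye(2))
        assert np.allclose(states.var(axis=0), np.diag(Sigma), rtol=0.08)

    def test_impulse_response_equals_matrix_power_recursion(self):
        A = np.array([[0.5, 0.2], [-0.1, 0.4]])
        truth = self._truth(A_true=A, D_true=np.ones(2))
        ev = pd.DataFrame({"onset": [1.0], "duration": [0.01],
                           "trial_type": ["oddball"], "response_time": [0.3]})
        states, _, inputs = simulate_latent_eeg(truth, ev, 3.0)
        t0 = int(np.flatnonzero(inputs.exogenous)[0])
        # brute-force recursion oracle
        expected = np.zeros_like(states)
        s = np.zeros(2)
        for t in range(states.shape[0]):
            At = A + truth.B_true[0] * inputs.modulatory[0, t]
            s = At @ s + inputs.exogenous[t] * np.ones(2)
            expected[t] = s
        assert np.allclose(states, expected, atol=1e-12)
        assert np.allclose(states[t0 + 3], np.linalg.matrix_power(A, 3)
                           @ np.ones(2), atol=1e-12)

    def test_unstable_truth_rejected_before_simulation(self):
        truth = self._truth(A_true=1.1 * np.eye(2))
        with pytest.raises(ValueError, match="unstable"):
            simulate_latent_eeg(truth, self._no_events(), 1.0)

    def test_zero_order_hold_upsampling(self):
        truth = self._truth(A_true=0.5 * np.eye(2), state_noise_prec=1.0,
                            eeg_fs_multiple=3)
        rng = np.random.default_rng(2)
        states, eeg, _ = simulate_latent_eeg(truth, self._no_events(),
                                             2.0, rng=rng)
        assert eeg.shape[0] == 3 * states.shape[0]
        assert np.allclose(eeg[0::3], eeg[1::3])


class TestPupil:
    def _one_trial(self):
        return pd.DataFrame({"onset": [10.0], "duration": [0.2],
                             "trial_type": ["oddball"],
                             "response_time": [0.4]})

    def test_constant_without_amplitude_or_noise(self):
        trace = simulate_pupil(self._one_trial(), subject_amp=0.0,
                               duration=15.0)
        assert np.allclose(trace.diameter, 1000.0)

    def test_peak_at_kernel_mode(self):
        trace = simulate_pupil(self._one_trial(), subject_amp=8.0,
                               duration=15.0)
        t_peak = np.argmax(trace.diameter) / trace.fs
        assert t_peak == pytest.approx(10.0 + 1.4, abs=1.0 / trace.fs)

    def test_planted_amplitude_equals_tepr_exactly(self):
        trace = simulate_pupil(self._one_trial(), subject_amp=8.0,
                               duration=15.0)
        table = compute_tepr(epoch_pupil(trace, self._one_trial()))
        assert table.subject_mean == pytest.approx(8.0, abs=1e-9)

    def test_kernel_unit_peak_and_unimodal(self):
        t = np.linspace(0.0, 6.0, 6001)
        k = pupil_kernel(t, peak=1.4)
        assert k.max() == pytest.approx(1.0, abs=1e-12)
        assert t[np.argmax(k)] == pytest.approx(1.4, abs=1e-3)
        peak_idx = np.argmax(k)
        assert np.all(np.diff(k[:peak_idx]) >= 0)
        assert np.all(np.diff(k[peak_idx:]) <= 0)


class TestBold:
    def _events(self):
        spec = ParadigmSpec(n_trials_per_run=12, first_k_standard=2,
                            rng_seed=3)
        return generate_event_schedule(spec)

    def test_zero_betas_zero_noise_gives_zero(self):
        ev = self._events()
        stv = np.zeros(len(ev))
        betas = pd.DataFrame({"event_oddball": [0.0], "event_standard": [0.0]})
        bold, _ = simulate_bold_rois(ev, stv, betas, n_vols=40)
        assert not bold.any()

    def test_default_acquisition_covers_315_seconds(self):
        assert 150 * 2.1 == pytest.approx(315.0)

    def test_planted_stv_beta_recovered_noiselessly(self):
        from pupilec.fmri_design_glm import HRFSpec, build_design, fit_glm
        ev = self._events()
        rng = np.random.default_rng(0)
        stv = rng.normal(size=len(ev))
        stv -= stv.mean()
        betas = pd.DataFrame({"stv_oddball": [2.5], "event_oddball": [1.0]})
        bold, _ = simulate_bold_rois(ev, stv, betas, n_vols=40)
        design = build_design(ev, stv=stv, confounds=None, tr=2.1, n_vols=40,
                              hrf=HRFSpec(), include_derivatives=False)
        res = fit_glm(bold, design)
        assert res.betas.loc["roi_0", "stv_oddball"] == pytest.approx(
            2.5, rel=1e-6)


class TestCohort:
    def test_same_seed_reproduces_cohort_exactly(self):
        spec = ParadigmSpec(n_trials_per_run=8, first_k_standard=2,
                            n_runs=1, n_subjects=3)
        truth = default_ground_truth(n_nodes=4, seed=1)
        a = generate_cohort(spec, truth, seed=5, with_bold=False)
        b = generate_cohort(spec, truth, seed=5, with_bold=False)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.coupling_gain == sb.coupling_gain
            for ra, rb in zip(sa.runs, sb.runs):
                assert np.array_equal(ra.eeg, rb.eeg)
                assert np.array_equal(ra.pupil.diameter, rb.pupil.diameter)
                pd.testing.assert_frame_equal(ra.events, rb.events)

    def test_zero_rho_gives_near_zero_sample_correlation(self):
        from pupilec.synthetic_data import draw_subject_effects
        truth = default_ground_truth(n_nodes=4, seed=1, planted_rho=0.0)
        gains, amps = draw_subject_effects(truth, 10_000,
                                           np.random.default_rng(0))
        assert abs(np.corrcoef(gains, amps)[0, 1]) < 0.03

    def test_too_few_subjects_rejected(self):
        spec = ParadigmSpec(n_trials_per_run=8, first_k_standard=2,
                            n_subjects=2)
        truth = default_ground_truth(n_nodes=4, seed=1)
        with pytest.raises(ValueError, match="3 subjects"):
            generate_cohort(spec, truth)

    def test_recovery_truth_snr_calibration(self):
        truth = recovery_ground_truth(seed=0, snr=5.0)
        rng = np.random.default_rng(3)
        ev = pd.DataFrame({"onset": [], "duration": [], "trial_type": [],
                           "response_time": []})
        states, eeg_clean, _ = simulate_latent_eeg(
            truth, ev, 100.0, rng=np.random.default_rng(3))
        H = truth.leadfield_L @ truth.indicator_G
        sig_power = np.mean((states @ H.T) ** 2)
        noise_power = 1.0 / truth.obs_noise_prec
        assert np.sqrt(sig_power / noise_power) == pytest.approx(5.0, rel=0.1)
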