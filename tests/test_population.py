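"""Population normalization, trial detection, correlation decay fits."""

import numpy as np
import pytest

from planexec.core import BehaviorTrace, InvalidConfigError, Session, SortedUnit
from planexec.population import (DecayFit, PopulationMatrix, TrialSet,
                                 behavioral_frequency, decay_timecourse,
                                 detect_trials, fit_decay,
                                 preprocess_population,
                                 trial_correlation_matrix, _column_normalize)
from planexec.synth import generate_ar1_population


class TestPreprocess:
    def test_column_contracts_without_global_mode(self, small_session):
        pop = preprocess_population(small_session, remove_global_mode=False)
        norms = np.linalg.norm(pop.matrix, axis=0)
        nz = norms > 0
        np.testing.assert_allclose(norms[nz], 1.0, atol=1e-9)
        np.testing.assert_allclose(pop.matrix[:, nz].mean(axis=0), 0.0, atol=1e-9)

    def test_global_mode_removed_and_norms_never_grow(self, small_session):
        pop = preprocess_population(small_session, remove_global_mode=True)
        assert pop.global_mode is not None
        assert abs(np.linalg.norm(pop.global_mode) - 1.0) < 1e-9
        proj = pop.global_mode @ pop.matrix
        np.testing.assert_allclose(proj, 0.0, atol=1e-9)
        assert np.all(np.linalg.norm(pop.matrix, axis=0) <= 1.0 + 1e-9)

    def test_two_unit_toy_z_scores_by_hand(self):
        # rates [[1,2],[4,3]] → row z-scores [[-1,1],[1,-1]] → columns demeaned
        # (already zero-mean) → unit norm: each column ±[1,-1]/√2
        m = np.array([[1.0, 2.0], [4.0, 3.0]])
        z = (m - m.mean(axis=1, keepdims=True)) / m.std(axis=1, keepdims=True)
        out = _column_normalize(z)
        np.testing.assert_allclose(out, [[-1 / np.sqrt(2), 1 / np.sqrt(2)],
                                         [1 / np.sqrt(2), -1 / np.sqrt(2)]])

    def test_silent_unit_excluded(self, behavior120):
        units = [SortedUnit(np.sort(np.random.default_rng(1).uniform(0, 120, 500))),
                 SortedUnit(np.sort(np.random.default_rng(2).uniform(0, 120, 500))),
                 SortedUnit(np.array([]))]
        s = Session(behavior=behavior120, units=units)
        pop = preprocess_population(s)
        assert pop.excluded == [2]
        assert pop.n_units == 2

    def test_single_unit_rejected(self, behavior120):
        s = Session(behavior=behavior120, units=[SortedUnit(np.array([1.0]))])
        with pytest.raises(InvalidConfigError):
            preprocess_population(s)


class TestTrials:
    def test_constant_speed_yields_no_trials(self):
        rng = np.random.default_rng(0)
        b = BehaviorTrace(vx=2.0 + 0.01 * rng.standard_normal(20000),
                          vy=np.zeros(20000))
        assert detect_trials(b).n_trials == 0

    def test_single_speed_step_yields_one_trial(self):
        n = 20000
        vx = np.where(np.arange(n) < 10000, 1.0, 3.0).astype(float)
        b = BehaviorTrace(vx=vx, vy=np.zeros(n))
        trials = detect_trials(b)
        assert trials.n_trials == 1
        assert abs(trials.centers[0] - 100.0) < 2.0  # near the step at t = 100 s

    def test_trial_window_is_1601_bins(self):
        assert TrialSet(centers=np.array([50.0])).bins_per_trial == 1601

    def test_session_too_short_rejected(self):
        b = BehaviorTrace(vx=np.ones(1000), vy=np.zeros(1000))
        with pytest.raises(InvalidConfigError):
            detect_trials(b)

    def test_detected_on_generated_behavior(self, behavior600):
        trials = detect_trials(behavior600)
        assert trials.n_trials > 0
        w = trials.half_window
        assert np.all((trials.centers >= w) &
                      (trials.centers <= behavior600.duration - w))


def _pop_from_matrix(m, dt=0.01):
    return PopulationMatrix(matrix=m, dt=dt)


class TestCorrelationMatrix:
    def test_identical_population_vector_gives_all_ones(self):
        col = np.array([1.0, 2.0, -1.0])
        col = (col - col.mean())
        col /= np.linalg.norm(col)
        m = np.tile(col[:, None], (1, 2000))
        trials = TrialSet(centers=np.array([10.0]))
        M = trial_correlation_matrix(_pop_from_matrix(m), trials)
        np.testing.assert_allclose(M, 1.0, atol=1e-12)

    def test_white_noise_offdiagonal_near_zero(self, rng):
        U = 64
        m = _column_normalize(rng.standard_normal((U, 2000)))
        trials = TrialSet(centers=np.array([10.0]))
        M = trial_correlation_matrix(_pop_from_matrix(m), trials)
        off = M[~np.eye(M.shape[0], dtype=bool)]
        se = 1.0 / np.sqrt(U)  # analytic SE of a random inner product
        assert abs(off.mean()) < 3 * se / np.sqrt(off.size / M.shape[0])
        assert off.std() < 2 * se

    def test_matrix_is_symmetric(self, rng):
        m = _column_normalize(rng.standard_normal((10, 2000)))
        trials = TrialSet(centers=np.array([10.0]))
        M = trial_correlation_matrix(_pop_from_matrix(m), trials)
        np.testing.assert_allclose(M, M.T, atol=1e-12)

    def test_zero_trials_rejected(self, rng):
        m = _column_normalize(rng.standard_normal((4, 2000)))
        with pytest.raises(InvalidConfigError):
            trial_correlation_matrix(_pop_from_matrix(m), TrialSet(centers=np.array([])))


class TestDecayFit:
    def test_exact_exponential_self_consistency(self):
        d = np.abs(np.subtract.outer(np.arange(1601), np.arange(1601))) * 0.01
        M = np.exp(-d / 0.3)
        fit = fit_decay(M, 800)
        assert abs(fit.tau - 0.3) < 1e-6
        assert abs(fit.amplitude - 1.0) < 1e-6

    def test_cutoff_frequency_is_reciprocal_tau(self):
        fit = DecayFit(tau=0.4, amplitude=1.0, reference_time=0.0, residual=0.0)
        assert fit.cutoff_frequency == pytest.approx(2.5)

    def test_nonpositive_correlations_rejected(self):
        M = -np.ones((100, 100))
        with pytest.raises(InvalidConfigError):
            fit_decay(M, 50)

    def test_tau_invariant_to_unit_permutation(self, rng):
        m = generate_ar1_population(30, 4000, 0.4, seed=3)
        mm = _column_normalize(m - m.mean(axis=1, keepdims=True))
        trials = TrialSet(centers=np.array([20.0]))
        t1 = fit_decay(trial_correlation_matrix(_pop_from_matrix(mm), trials), 800).tau
        perm = rng.permutation(30)
        t2 = fit_decay(trial_correlation_matrix(_pop_from_matrix(mm[perm]), trials), 800).tau
        # identical up to curve_fit's numerical tolerance
        assert t1 == pytest.approx(t2, rel=1e-6)

    def test_timecourse_reports_premove_and_move(self):
        d = np.abs(np.subtract.outer(np.arange(1601), np.arange(1601))) * 0.01
        M = np.exp(-d / 0.5)
        df = decay_timecourse(M, step=0.5)
        assert abs(df.attrs["tau_premove"] - 0.5) < 0.01
        assert abs(df.attrs["tau_move"] - 0.5) < 0.01
        assert np.isfinite(df["tau_s"]).all()


class TestBehavioralFrequency:
    def test_fast_content_needs_higher_cutoff(self, behavior600):
        f_est = behavioral_frequency(behavior600)
        assert f_est >= 1.0  # sub-movement content sits well above 1 Hz

    def test_pure_noise_resolves_at_lowest_band(self):
        rng = np.random.default_rng(0)
        b = BehaviorTrace(vx=0.5 * rng.standard_normal(20000),
                          vy=0.5 * rng.standard_normal(20000),
                          tracking_noise_sd=0.79)
        assert behavioral_frequency(b) == pytest.approx(0.11, abs=0.01)
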