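"""AWD construction, modulation metrics and the segment bootstrap."""

import numpy as np
import pytest

from planexec.core import BehaviorTrace, InvalidConfigError
from planexec.modulation import (AWDTable, bootstrap_duration, compute_awd,
                                 instantaneous_rate, modulation_metrics,
                                 planning_sensory_index)
from planexec.synth import BehaviorConfig, UnitSpec, generate_behavior, unit_rate


def brute_force_awd(activity, behavior, lag_bins):
    """Literal double-loop oracle: mean activity(t + k) given speed(t) bin."""
    speed = behavior.speed()
    vmin, vmax = speed.min(), speed.max()
    idx = np.clip(((speed - vmin) / (vmax - vmin) * 10).astype(int), 0, 9)
    n = activity.size
    out = np.full((len(lag_bins), 10), np.nan)
    for i, k in enumerate(lag_bins):
        for b in range(10):
            vals = [activity[t + k] for t in range(n)
                    if idx[t] == b and 0 <= t + k < n]
            if vals:
                out[i, b] = np.mean(vals)
    return out


class TestInstantaneousRate:
    def test_single_spike_gaussian_bump_of_unit_area(self):
        r = instantaneous_rate(np.array([5.0]), duration=10.0)
        assert abs(r.sum() * 0.01 - 1.0) < 1e-6
        assert abs(np.argmax(r) - 500) <= 1
        # two spikes 1 s apart leave the midpoint at ≈ 0 (σ = 50 ms)
        r2 = instantaneous_rate(np.array([4.0, 6.0]), duration=10.0)
        assert r2[500] < 1e-6

    def test_homogeneous_rate_recovered(self, rng):
        times = np.sort(rng.uniform(0, 600, 6000))
        r = instantaneous_rate(times, duration=600.0)
        assert abs(r.mean() - 10.0) < 0.5

    def test_empty_train_gives_zeros(self):
        assert not instantaneous_rate(np.array([]), duration=5.0).any()


class TestAWD:
    def test_matches_brute_force_oracle(self, behavior120):
        short = BehaviorTrace(vx=behavior120.vx[:3000], vy=behavior120.vy[:3000],
                              dt=behavior120.dt)
        rng = np.random.default_rng(1)
        act = rng.random(3000)
        table = compute_awd(act, short, max_lag=0.5)
        lag_bins = np.arange(-50, 51)
        expected = brute_force_awd(act, short, lag_bins)
        np.testing.assert_allclose(table.values, expected, atol=1e-10)

    def test_constant_activity_has_zero_modulation(self, behavior120):
        table = compute_awd(np.full(behavior120.n_bins, 3.0), behavior120)
        np.testing.assert_allclose(table.modulation()[np.isfinite(table.modulation())],
                                   0.0, atol=1e-12)

    def test_future_speed_coupling_peaks_at_negative_lag(self, behavior600):
        # activity(t) = speed(t + 0.2 s): the unit leads the movement, so the
        # modulation must peak at lag −0.2 s (planning side)
        speed = behavior600.speed()
        act = np.empty_like(speed)
        act[:-20] = speed[20:]
        act[-20:] = speed[-1]
        prof = modulation_metrics(compute_awd(act, behavior600))
        assert abs(prof.lag + 0.2) <= 0.03
        assert prof.modulated

    def test_shift_control_is_unmodulated(self, behavior600):
        speed = behavior600.speed()
        act = np.roll(speed, 2000)  # circular shift by 20 s destroys the coupling
        prof = modulation_metrics(compute_awd(act, behavior600))
        assert not prof.modulated

    def test_constant_speed_is_degenerate(self):
        b = BehaviorTrace(vx=np.full(2000, 2.0), vy=np.zeros(2000))
        with pytest.raises(InvalidConfigError):
            compute_awd(np.ones(2000), b)

    def test_time_reversal_flips_the_lag_axis(self, behavior120):
        rng = np.random.default_rng(3)
        act = rng.random(behavior120.n_bins)
        fwd = compute_awd(act, behavior120, max_lag=0.5)
        rev_b = BehaviorTrace(vx=behavior120.vx[::-1].copy(),
                              vy=behavior120.vy[::-1].copy(), dt=behavior120.dt)
        rev = compute_awd(act[::-1].copy(), rev_b, max_lag=0.5)
        np.testing.assert_allclose(rev.values, fwd.values[::-1], atol=1e-10)

    def test_modulation_invariant_to_constant_offset(self, behavior120):
        rng = np.random.default_rng(4)
        act = rng.random(behavior120.n_bins)
        m1 = compute_awd(act, behavior120).modulation()
        m2 = compute_awd(act + 7.5, behavior120).modulation()
        np.testing.assert_allclose(m1, m2, atol=1e-9)


def _table_from_curve(curve, dt=0.01):
    """AWD table whose 10 bins all carry the given modulation curve."""
    lags = (np.arange(curve.size) - curve.size // 2) * dt
    values = np.tile(curve[:, None], (1, 10))
    counts = np.ones_like(values, dtype=np.int64)
    return AWDTable(lags=lags, bin_edges=np.linspace(0, 1, 11), values=values,
                    counts=counts, dt=dt)


class TestMetrics:
    def test_gaussian_curve_duration_closed_form(self):
        # the ≥ 80 %-of-peak width of a Gaussian is 2σ√(2 ln 1.25) ≈ 1.336 σ
        dt = 0.01
        lags = (np.arange(801) - 400) * dt
        for sigma in (0.2, 0.5, 1.0):
            curve = np.exp(-0.5 * (lags / sigma) ** 2)
            prof = modulation_metrics(_table_from_curve(curve))
            expected = 2.0 * sigma * np.sqrt(2.0 * np.log(1.25))
            assert abs(prof.duration - expected) <= 2 * dt
            assert abs(prof.lag) <= dt

    def test_flat_curve_flagged_and_capped(self):
        prof = modulation_metrics(_table_from_curve(np.zeros(801)))
        assert not prof.modulated
        assert prof.capped

    def test_wide_plateau_capped_at_lag_range(self):
        prof = modulation_metrics(_table_from_curve(np.ones(801) +
                                                    1e-3 * np.cos(np.arange(801))))
        assert prof.capped
        assert prof.duration <= 8.0 + 1e-9


class TestPlanningSensoryIndex:
    @pytest.mark.parametrize("center,expected", [(-0.5, 100.0), (0.5, -100.0)])
    def test_one_sided_mass_saturates(self, center, expected):
        lags = (np.arange(801) - 400) * 0.01
        curve = np.exp(-0.5 * ((lags - center) / 0.05) ** 2)
        prof = modulation_metrics(_table_from_curve(curve))
        assert abs(planning_sensory_index(prof) - expected) < 1.0

    def test_mirrored_mass_cancels(self):
        lags = (np.arange(801) - 400) * 0.01
        curve = (np.exp(-0.5 * ((lags + 0.5) / 0.05) ** 2)
                 + np.exp(-0.5 * ((lags - 0.5) / 0.05) ** 2))
        prof = modulation_metrics(_table_from_curve(curve))
        assert abs(planning_sensory_index(prof)) < 2.0

    def test_empty_windows_return_nan(self):
        prof = modulation_metrics(_table_from_curve(np.zeros(801)))
        assert np.isnan(planning_sensory_index(prof))


class TestBootstrap:
    def test_noise_free_unit_has_small_relative_sd(self, behavior600):
        spec = UnitSpec(lag=-0.2, modulation_sigma=0.15, gain=2.5, baseline_rate=3.0)
        rate = unit_rate(behavior600, spec)
        sd, durations = bootstrap_duration(rate, behavior600, n_reps=30, seed=0)
        assert sd < 0.25 * durations.mean()

    def test_sd_shrinks_with_session_length(self):
        # a smooth, well-modulated unit: the 80 %-width statistic is only
        # stable enough for clean length scaling when the modulation curve
        # is unimodal, so the unit has a wide blur and a strong gain
        spec = UnitSpec(lag=-0.2, modulation_sigma=0.3, gain=4.0, baseline_rate=4.0)
        ratios = []
        for seed in range(3):
            sds = []
            for dur in (300.0, 1200.0):
                b = generate_behavior(BehaviorConfig(duration=dur), seed=seed)
                from planexec.synth import generate_session
                from planexec.modulation import instantaneous_rate as irate
                s = generate_session(b, [spec], seed=seed + 20)
                act = irate(s.units[0], s.duration)
                import warnings

                with warnings.catch_warnings():  # 300 s → short-segment warning
                    warnings.simplefilter("ignore", UserWarning)
                    sd, _ = bootstrap_duration(act, b, n_reps=40, seed=seed)
                sds.append(sd)
            ratios.append(sds[0] / max(sds[1], 1e-9))
        # quadrupling the data shrinks the SD by roughly √4 on average
        assert np.mean(ratios) > 1.2

    def test_config_validation(self, behavior120):
        act = np.ones(behavior120.n_bins)
        with pytest.raises(InvalidConfigError):
            bootstrap_duration(act, behavior120, n_segments=1)
        with pytest.raises(InvalidConfigError):
            bootstrap_duration(act, behavior120, n_reps=5)

    def test_short_segments_warn(self, behavior120):
        rng = np.random.default_rng(5)
        act = rng.random(behavior120.n_bins)
        with pytest.warns(UserWarning, match="shorter than 10 s"):
            bootstrap_duration(act, behavior120, n_segments=100, n_reps=10, seed=0)
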