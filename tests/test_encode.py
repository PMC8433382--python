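"""Encoding/decoding kernels, the frequency sweep, and kernel analyses."""

import numpy as np
import pytest

from planexec.core import BehaviorTrace, InvalidConfigError, Session, SortedUnit
from planexec.encode import (KERNEL_T, fit_encoding, kernel_lags, lagged_design,
                             morse_cwt, two_point_decode_sweep,
                             unit_kernel_analysis, _rise_latency)
from planexec.synth import (BehaviorConfig, UnitSpec, generate_behavior,
                            generate_session, unit_rate)


def _session_with_rates(behavior, n_units, seed):
    rng = np.random.default_rng(seed)
    units = [SortedUnit(np.sort(rng.uniform(0, behavior.duration, 200)))
             for _ in range(n_units)]
    return Session(behavior=behavior, units=units)


class TestEncoding:
    def test_kernel_grid_is_400_taps(self):
        lags = kernel_lags()
        assert lags.size == KERNEL_T == 400
        assert lags[0] == pytest.approx(-2.0)
        assert lags[-1] == pytest.approx(1.99)

    def test_exact_linear_model_recovered(self, behavior120):
        # activity generated exactly as kernel · velocity → exact recovery
        rng = np.random.default_rng(6)
        lag_bins = np.arange(KERNEL_T) - KERNEL_T // 2
        true_k = np.zeros((KERNEL_T, 2))
        true_k[190:210, 0] = rng.standard_normal(20)
        true_k[195:205, 1] = rng.standard_normal(10)
        X = np.concatenate([lagged_design(behavior120.vx, lag_bins),
                            lagged_design(behavior120.vy, lag_bins)], axis=1)
        act = X @ true_k.reshape(-1, order="F") + 5.0
        s = _session_with_rates(behavior120, 1, seed=0)
        enc = fit_encoding(s, activities=act[None, :])
        rms = np.sqrt(np.mean((enc.kernels[0] - true_k) ** 2))
        assert rms < 1e-6
        assert enc.r2[0] > 1.0 - 1e-9

    def test_out_of_support_lag_encodes_worse(self, behavior600):
        inside = UnitSpec(lag=-0.5, modulation_sigma=0.1, gain=3.0, baseline_rate=3.0,
                          drive="vx")
        outside = UnitSpec(lag=-3.0, modulation_sigma=0.1, gain=3.0, baseline_rate=3.0,
                           drive="vx")
        acts = np.stack([unit_rate(behavior600, inside),
                         unit_rate(behavior600, outside)])
        s = _session_with_rates(behavior600, 2, seed=1)
        enc = fit_encoding(s, activities=acts)
        assert enc.r2[0] > enc.r2[1] + 0.2

    def test_noisy_variant_matches_residual_variance(self, small_session):
        enc = fit_encoding(small_session)
        noisy = enc.noisy(seed=0)
        resid_sd = (noisy - enc.denoised).std(axis=1)
        np.testing.assert_allclose(resid_sd, enc.residual_sd, rtol=0.05)

    def test_short_session_rejected(self):
        b = BehaviorTrace(vx=np.random.default_rng(0).standard_normal(1000),
                          vy=np.zeros(1000))
        with pytest.raises(InvalidConfigError):
            fit_encoding(Session(behavior=b, units=[SortedUnit(np.array([1.0]))]))


class TestTwoPointSweep:
    def test_unit_permutation_invariance(self, behavior120, rng):
        acts = rng.standard_normal((5, behavior120.n_bins))
        acts[0] += 0.5 * behavior120.vx
        d1 = two_point_decode_sweep(acts, behavior120)
        d2 = two_point_decode_sweep(acts[::-1].copy(), behavior120)
        np.testing.assert_allclose(d1["performance"], d2["performance"], atol=1e-9)

    def test_pure_noise_units_decode_nothing(self, behavior120, rng):
        acts = rng.standard_normal((4, behavior120.n_bins))
        df = two_point_decode_sweep(acts, behavior120)
        # 8 free weights on n ≈ 12000 samples: chance level ~ √(8/n)
        assert np.nanmax(np.abs(df["performance"])) < 5 * np.sqrt(8 / behavior120.n_bins)

    def test_information_processing_inequality(self, behavior120):
        # decoding the encoder's prediction can never beat decoding the
        # noiseless ground-truth rates it was fit to approximate
        # keep the coupling strictly linear (high baseline, small gain, so the
        # rate floor at zero never binds) — the inequality is about a linear
        # ground truth, and rectification would itself hurt a linear decoder
        specs = [UnitSpec(lag=0.0, modulation_sigma=0.05, gain=1.0,
                          baseline_rate=12.0, drive=d) for d in ("vx", "vy", "vx")]
        truth = np.stack([unit_rate(behavior120, sp) for sp in specs])
        assert np.all(truth > 0)  # floor never engaged
        rng = np.random.default_rng(8)
        noisy = truth + 2.0 * rng.standard_normal(truth.shape)
        s = _session_with_rates(behavior120, 3, seed=2)
        enc = fit_encoding(s, activities=noisy)
        perf_enc = two_point_decode_sweep(enc.denoised, behavior120)["performance"]
        perf_truth = two_point_decode_sweep(truth, behavior120)["performance"]
        assert np.nanmean(perf_enc) <= np.nanmean(perf_truth) + 0.02


class TestMorseCWT:
    def test_sinusoid_ridge_at_its_frequency(self):
        dt = 0.01
        t = np.arange(0, 40, dt)
        x = np.sin(2 * np.pi * 3.0 * t)
        freqs, W = morse_cwt(x, dt)
        ridge = freqs[np.argmax(np.abs(W[:, 1000:3000]).mean(axis=1))]
        assert ridge == pytest.approx(3.0, rel=0.08)

    def test_analytic_output_energy_concentrated(self):
        dt = 0.01
        t = np.arange(0, 20, dt)
        x = np.cos(2 * np.pi * 1.0 * t)
        freqs, W = morse_cwt(x, dt, freqs=np.array([1.0]))
        # analytic wavelet of a unit cosine has |W| ≈ amplitude (≈ 1)
        assert np.median(np.abs(W[0, 200:-200])) == pytest.approx(1.0, rel=0.1)


class TestKernelGeometry:
    def test_triangular_kernel_half_rise_latency(self):
        lags = kernel_lags()
        half_width = 0.5
        kernel = np.maximum(0.0, 1.0 - np.abs(lags) / half_width)
        # rising flank crosses 50 % at −half_width/2
        assert _rise_latency(kernel, lags) == pytest.approx(-half_width / 2, abs=0.01)

    def test_jittered_kernels_recover_latency_sd(self, rng):
        lags = kernel_lags()
        jitter_sd = 0.1
        lats = []
        for _ in range(200):
            shift = rng.normal(0.0, jitter_sd)
            k = np.exp(-0.5 * ((lags - (-0.3 + shift)) / 0.08) ** 2)
            lats.append(_rise_latency(k, lags))
        assert np.std(lats) == pytest.approx(jitter_sd, rel=0.2)

    def test_unit_kernel_analysis_pipeline(self, behavior300):
        specs = [UnitSpec(lag=-0.1, modulation_sigma=0.06,
                          gain=3.0 * (-1.0) ** i, baseline_rate=10.0,
                          drive="vx") for i in range(5)]
        s = generate_session(behavior300, specs, seed=12)
        res = unit_kernel_analysis(s, n_boot=20, seed=13)
        assert res.kernels.shape == (5, 2, KERNEL_T)
        assert res.wavelet_mean.shape[1] == KERNEL_T
        assert np.isfinite(res.latency_sd)
        assert res.weight_boot_sd is not None and np.all(res.weight_boot_sd >= 0)
        # kernel energy concentrates around the true unit lag of −0.1 s
        near = np.abs(res.lags + 0.1) <= 0.3
        far = np.abs(res.lags) >= 1.0
        k = np.stack([res.kernels[u, res.dominant_axis[u]] for u in range(5)])
        assert np.abs(k[:, near]).mean() > 2.0 * np.abs(k[:, far]).mean()

    def test_too_few_units_rejected(self, small_session, behavior120):
        s = Session(behavior=behavior120, units=small_session.units[:2])
        with pytest.raises(InvalidConfigError):
            unit_kernel_analysis(s)
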