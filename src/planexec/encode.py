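"""Linear encoding (de-noising), frequency-swept decoding, and kernel analyses.

Encoding: each unit's smoothed firing rate is predicted from the lagged
2-D paw velocity through a T × 2 least-squares kernel (T = 400 taps on the
−2…2 s / 10 ms grid).  The prediction is the *de-noised* activity — it has
orders of magnitude fewer free parameters than the raw trace, which
removes the noise advantage low frequencies would otherwise enjoy in
decoding comparisons.  A noise-matched variant adds white Gaussian noise
with the raw residual variance back onto the de-noised activity.

Two-point decoding sweep: per frequency band, the band-passed activity of
all units is mapped to each velocity axis with only two weights per unit,
at lags −1/f and 0 relative to behavior.  Restricting the decoder to two
taps prevents it from trivially inverting the encoder; the performance
curve across bands then reflects which neural frequency carries the
velocity signal.

Unit-specific decoding kernels: one T × 1 kernel per unit and axis mapping
that unit's activity to velocity, analysed with a generalized Morse
continuous wavelet transform (symmetry 1.5, time–bandwidth product 2),
the time of the largest rectified temporal derivative, 50 %-of-extremum
rise latencies, and a 10 s-segment bootstrap of the kernel weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BehaviorTrace, InvalidConfigError, Session
from .filtering import BandSpec, DEFAULT_BANDS, band_pass
from .modulation import instantaneous_rate

__all__ = [
    "KERNEL_T",
    "kernel_lags",
    "lagged_design",
    "EncodingResult",
    "fit_encoding",
    "two_point_decode_sweep",
    "UnitKernelResult",
    "unit_kernel_analysis",
    "morse_cwt",
]

KERNEL_T = 400          # taps of the temporal kernel (−2…2 s at 10 ms)
KERNEL_HALF = KERNEL_T // 2


def kernel_lags(dt: float = 0.01) -> np.ndarray:
    """Lag (s) of each kernel tap: −2.00 … +1.99 s at 10 ms."""
    return (np.arange(KERNEL_T) - KERNEL_HALF) * dt


def lagged_design(x: np.ndarray, lag_bins: np.ndarray) -> np.ndarray:
    """Design matrix with columns x(t + k) for each integer lag k.

    Out-of-range samples are zero — with session-long traces the edge
    contribution is negligible.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    out = np.zeros((n, lag_bins.size))
    for j, k in enumerate(lag_bins):
        if k >= 0:
            out[: n - k, j] = x[k:]
        else:
            out[-k:, j] = x[:k]
    return out


def _ols(X: np.ndarray, Y: np.ndarray, ridge: float = 0.0) -> tuple[np.ndarray, bool]:
    """Least squares via normal equations; falls back to a ridge solve.

    Returns (weights, regularized_flag).  X and Y are assumed demeaned.
    """
    G = X.T @ X
    b = X.T @ Y
    if ridge > 0:
        G = G + ridge * np.eye(G.shape[0])
    try:
        w = np.linalg.solve(G, b)
        if np.all(np.isfinite(w)):
            return w, ridge > 0
    except np.linalg.LinAlgError:
        pass
    lam = 1e-8 * max(np.trace(G) / G.shape[0], 1.0)
    w = np.linalg.solve(G + lam * np.eye(G.shape[0]), b)
    return w, True


def _session_rates(session: Session, dt: float, rate_sigma: float) -> np.ndarray:
    return np.stack([
        instantaneous_rate(u, session.duration, dt=dt, sigma=rate_sigma)
        for u in session.units
    ])


@dataclass
class EncodingResult:
    """Per-unit encoding kernels and the de-noised activity."""

    kernels: np.ndarray        # (units × T × 2), axes order (vx, vy)
    denoised: np.ndarray       # (units × bins)
    residual_sd: np.ndarray    # (units,)
    r2: np.ndarray             # (units,) in-sample
    dt: float
    flags: list[str] = field(default_factory=list)

    def noisy(self, seed: int = 0) -> np.ndarray:
        """De-noised activity plus white noise matching the raw residual SD."""
        rng = np.random.default_rng(seed)
        return self.denoised + rng.normal(
            0.0, self.residual_sd[:, None], self.denoised.shape
        )


def fit_encoding(
    session: Session,
    dt: float = 0.01,
    rate_sigma: float = 0.05,
    activities: np.ndarray | None = None,
) -> EncodingResult:
    """Fit the T × 2 velocity→activity kernel of every unit by OLS.

    ``activities`` overrides the smoothed instantaneous rates (units ×
    bins) when the continuous activity is already available.
    """
    if session.duration < 60.0:
        raise InvalidConfigError("encoding needs a session of at least 60 s")
    rates = _session_rates(session, dt, rate_sigma) if activities is None else \
        np.atleast_2d(np.asarray(activities, dtype=float))
    b = session.behavior
    lag_bins = np.arange(KERNEL_T) - KERNEL_HALF
    Xx = lagged_design(b.vx, lag_bins)
    Xy = lagged_design(b.vy, lag_bins)
    X = np.concatenate([Xx, Xy], axis=1)
    mu = X.mean(axis=0, keepdims=True)
    Xc = X - mu
    flags: list[str] = []
    Yc = rates - rates.mean(axis=1, keepdims=True)
    W, regularized = _ols(Xc, Yc.T)
    if regularized:
        flags.append("rank-deficient velocity design; ridge-regularized solve")
    pred = (Xc @ W).T + rates.mean(axis=1, keepdims=True)
    resid = rates - pred
    residual_sd = resid.std(axis=1)
    var_y = rates.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(var_y > 0, 1.0 - resid.var(axis=1) / var_y, 0.0)
    kernels = np.stack([W[:KERNEL_T].T, W[KERNEL_T:].T], axis=2)
    return EncodingResult(kernels=kernels, denoised=pred, residual_sd=residual_sd,
                          r2=r2, dt=dt, flags=flags)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def two_point_decode_sweep(
    activities: np.ndarray,
    behavior: BehaviorTrace,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    split: bool = False,
) -> "pd.DataFrame":
    """Decoding performance vs frequency with a two-tap decoder.

    For each band the activity is band-passed and each velocity axis is
    regressed on 2·U predictors — every unit's activity at lags −1/f and 0
    relative to behavior.  Performance is the Pearson r between decoded and
    measured velocity, averaged over the two axes.  ``split`` switches from
    the in-sample fit to a blocked 2-fold split (fit one half, score the
    other, average).

    Returns a DataFrame (center_freq, lag_used_s, r_x, r_y, performance)
    with ``attrs['argmax_freq']`` set to the best band's center frequency.
    """
    import pandas as pd

    activities = np.atleast_2d(np.asarray(activities, dtype=float))
    dt = behavior.dt
    n = behavior.n_bins
    if activities.shape[1] != n:
        raise InvalidConfigError("activities and behavior must share the grid")
    targets = {"x": behavior.vx, "y": behavior.vy}
    rows = []
    for band in bands:
        bp = band_pass(activities, band, dt)
        if np.allclose(bp.std(axis=1), 0.0):
            rows.append(dict(center_freq=band.center_freq, lag_used_s=np.nan,
                             r_x=np.nan, r_y=np.nan, performance=np.nan,
                             flag="zero-variance activity; band skipped"))
            continue
        lag = int(round(1.0 / band.center_freq / dt))
        past = np.zeros_like(bp)
        past[:, lag:] = bp[:, :-lag] if lag > 0 else bp[:, :]
        X = np.concatenate([past, bp], axis=0).T       # n × 2U
        Xc = X - X.mean(axis=0, keepdims=True)
        r_axis = {}
        for ax, v in targets.items():
            vc = v - v.mean()
            if not split:
                w, _ = _ols(Xc, vc)
                r_axis[ax] = _pearson(Xc @ w, vc)
            else:
                h = n // 2
                rs = []
                for tr, te in (((0, h), (h, n)), ((h, n), (0, h))):
                    w, _ = _ols(Xc[tr[0]:tr[1]], vc[tr[0]:tr[1]])
                    rs.append(_pearson(Xc[te[0]:te[1]] @ w, vc[te[0]:te[1]]))
                r_axis[ax] = float(np.mean(rs))
        rows.append(dict(center_freq=band.center_freq, lag_used_s=lag * dt,
                         r_x=r_axis["x"], r_y=r_axis["y"],
                         performance=float(np.mean([r_axis["x"], r_axis["y"]])),
                         flag=""))
    df = pd.DataFrame(rows)
    if df["performance"].notna().any():
        df.attrs["argmax_freq"] = float(
            df.loc[df["performance"].idxmax(), "center_freq"]
        )
    return df


def morse_cwt(
    x: np.ndarray,
    dt: float,
    freqs: np.ndarray | None = None,
    gamma: float = 1.5,
    time_bandwidth: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous wavelet transform with a generalized Morse wavelet.

    ``gamma`` is the symmetry parameter and ``time_bandwidth`` the product
    P² = βγ, so β = time_bandwidth / gamma.  The analytic wavelet is
    evaluated in the frequency domain with unit peak value.  The default
    frequency grid uses 12 voices per octave between 0.25 and 30 Hz.

    Returns (freqs, W) with W complex of shape (len(freqs), len(x)).
    """
    x = np.asarray(x, dtype=float)
    beta = time_bandwidth / gamma
    if freqs is None:
        n_oct = np.log2(30.0 / 0.25)
        freqs = 0.25 * 2.0 ** (np.arange(int(np.floor(12 * n_oct)) + 1) / 12.0)
    freqs = np.asarray(freqs, dtype=float)
    n = x.size
    omega = 2.0 * np.pi * np.fft.fftfreq(n, d=dt)
    omega_peak = (beta / gamma) ** (1.0 / gamma)
    Xf = np.fft.fft(x)
    W = np.empty((freqs.size, n), dtype=complex)
    for i, f in enumerate(freqs):
        s = omega_peak / (2.0 * np.pi * f)
        w = s * omega
        psi = np.zeros(n)
        pos = w > 0
        # unit peak: ψ̂(ω_peak) = 2 with the analytic factor
        psi[pos] = 2.0 * np.exp(
            beta * np.log(w[pos] / omega_peak) - (w[pos] ** gamma - omega_peak ** gamma)
        )
        W[i] = np.fft.ifft(Xf * psi)
    return freqs, W


@dataclass
class UnitKernelResult:
    """Unit-specific decoding kernels and their temporal/spectral summaries."""

    lags: np.ndarray                 # (T,) s
    kernels: np.ndarray              # (units × 2 × T), axes (vx, vy)
    dominant_axis: np.ndarray        # (units,) 0 = x, 1 = y
    wavelet_freqs: np.ndarray
    wavelet_mean: np.ndarray         # (freqs × T) mean |W| across units
    derivative_peak_time: np.ndarray  # (units,) s
    rise_latency: np.ndarray         # (units,) s, 50 %-of-extremum crossing
    latency_sd: float
    weight_boot_sd: np.ndarray | None = None   # (T,) mean across units
    excluded: list[int] = field(default_factory=list)
    fit_r: np.ndarray | None = None  # (units × 2) in-sample decode r per axis


def _rise_latency(kernel: np.ndarray, lags: np.ndarray) -> float:
    """Time of the 50 %-of-extremum crossing on the rising flank.

    The extremum may be a maximum or a minimum; the crossing is searched
    backward in time from the extremum.
    """
    i_ext = int(np.argmax(np.abs(kernel)))
    target = 0.5 * abs(kernel[i_ext])
    sign = np.sign(kernel[i_ext]) or 1.0
    k = sign * kernel
    j = i_ext
    while j > 0 and k[j - 1] >= target:
        j -= 1
    if j == 0:
        return float(lags[0])
    # linear interpolation between the last sub-threshold and first supra sample
    k0, k1 = k[j - 1], k[j]
    frac = (target - k0) / (k1 - k0) if k1 != k0 else 0.0
    return float(lags[j - 1] + frac * (lags[j] - lags[j - 1]))


def unit_kernel_analysis(
    session: Session,
    dt: float = 0.01,
    rate_sigma: float = 0.05,
    activities: np.ndarray | None = None,
    bootstrap_segment_s: float = 10.0,
    n_boot: int = 50,
    seed: int = 0,
    ridge_alpha: float = 0.1,
) -> UnitKernelResult:
    """Per-unit T × 1 decoding kernels plus wavelet / latency summaries.

    Each unit's activity alone is regressed onto each velocity axis with a
    T-tap kernel.  The 400 lagged copies of a 50 ms-smoothed rate are
    strongly collinear, so the normal equations carry a small ridge
    (``ridge_alpha`` × mean eigenvalue of XᵀX) and only time bins with full
    ±2 s support enter the fit; without both, the solution is dominated by
    noise-amplifying oscillations.  All-zero kernels exclude the unit from
    latency stats.  Kernel-weight variability is estimated by bootstrapping
    10 s segments of the session (resampling per-segment normal equations).
    """
    if session.n_units < 5:
        raise InvalidConfigError("unit-kernel analysis needs ≥ 5 units")
    rates = _session_rates(session, dt, rate_sigma) if activities is None else \
        np.atleast_2d(np.asarray(activities, dtype=float))
    b = session.behavior
    lag_bins = np.arange(KERNEL_T) - KERNEL_HALF
    lags = kernel_lags(dt)
    valid = slice(KERNEL_HALF, rates.shape[1] - KERNEL_HALF)
    V = np.stack([b.vx[valid] - b.vx[valid].mean(),
                  b.vy[valid] - b.vy[valid].mean()])
    n = V.shape[1]
    seg = max(1, int(round(bootstrap_segment_s / dt)))
    bounds = np.arange(0, n + 1, seg)
    if bounds[-1] != n:
        bounds = np.append(bounds, n)
    n_seg = bounds.size - 1
    rng = np.random.default_rng(seed)

    U = rates.shape[0]
    kernels = np.zeros((U, 2, KERNEL_T))
    fit_r = np.zeros((U, 2))
    boot_sd_acc = np.zeros(KERNEL_T)
    boot_units = 0
    excluded: list[int] = []
    for u in range(U):
        Xc = lagged_design(rates[u], lag_bins)[valid]
        Xc = Xc - Xc.mean(axis=0, keepdims=True)
        ridge = ridge_alpha * max(np.einsum("ij,ij->", Xc, Xc) / KERNEL_T, 1e-12)
        W, _ = _ols(Xc, V.T, ridge=ridge)
        kernels[u] = W.T
        pred = Xc @ W
        for ax in range(2):
            fit_r[u, ax] = _pearson(pred[:, ax], V[ax])
        if np.allclose(kernels[u], 0.0):
            excluded.append(u)
            continue
        if n_boot > 0 and n_seg >= 2:
            ax = int(np.nanargmax(fit_r[u]))
            Gs = np.empty((n_seg, KERNEL_T, KERNEL_T))
            bs = np.empty((n_seg, KERNEL_T))
            for s in range(n_seg):
                sl = slice(bounds[s], bounds[s + 1])
                Gs[s] = Xc[sl].T @ Xc[sl]
                bs[s] = Xc[sl].T @ V[ax, sl]
            reps = np.empty((n_boot, KERNEL_T))
            for r in range(n_boot):
                pick = rng.integers(0, n_seg, size=n_seg)
                G = Gs[pick].sum(axis=0)
                rhs = bs[pick].sum(axis=0)
                lam = ridge_alpha * max(np.trace(G) / KERNEL_T, 1e-12)
                reps[r] = np.linalg.solve(G + lam * np.eye(KERNEL_T), rhs)
            boot_sd_acc += reps.std(axis=0)
            boot_units += 1

    # dominant axis = the one the unit actually predicts, not the larger-norm
    # kernel (a pure-noise kernel can out-norm a true one under collinearity)
    dominant = np.nanargmax(np.where(np.isfinite(fit_r), fit_r, -np.inf), axis=1)
    kept = [u for u in range(U) if u not in excluded]
    deriv_peak = np.full(U, np.nan)
    latency = np.full(U, np.nan)
    wavelet_maps = []
    wfreqs = None
    for u in kept:
        k = kernels[u, dominant[u]]
        d = np.abs(np.diff(k)) / dt
        deriv_peak[u] = float(lags[int(np.argmax(d))])
        latency[u] = _rise_latency(k, lags)
        wfreqs, W = morse_cwt(k, dt)
        wavelet_maps.append(np.abs(W))
    wavelet_mean = (np.mean(wavelet_maps, axis=0) if wavelet_maps
                    else np.zeros((0, KERNEL_T)))
    lat = latency[np.isfinite(latency)]
    return UnitKernelResult(
        lags=lags,
        kernels=kernels,
        dominant_axis=dominant,
        wavelet_freqs=wfreqs if wfreqs is not None else np.empty(0),
        wavelet_mean=wavelet_mean,
        derivative_peak_time=deriv_peak,
        rise_latency=latency,
        latency_sd=float(lat.std()) if lat.size else float("nan"),
        weight_boot_sd=boot_sd_acc / boot_units if boot_units else None,
        excluded=excluded,
        fit_r=fit_r,
    )
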