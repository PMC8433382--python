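"""Subtractive-Gaussian filtering of neural activity traces.

All band filtering is built from Gaussian smoothing with the cutoff
convention f = 1/(2πσ):

* high-pass  : x − G_σhp(x)
* band-pass  : G_σlp(x − G_σhp(x))
* envelope   : |band-pass|, optionally smoothed again

The default band table pairs seven high-pass σ values with seven low-pass
σ values; each band is labelled by the nominal cutoff of its low-pass
stage (11, 4.5, 2.2, 1.1, 0.45, 0.22 and 0.11 Hz).  The σ ratio between
the two stages is ≈ 4 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import hilbert
from scipy.stats import pearsonr

from .core import BehaviorTrace, InvalidConfigError

__all__ = [
    "BandSpec",
    "DEFAULT_BANDS",
    "LOW_PASS_BAND",
    "gaussian_smooth",
    "high_pass",
    "band_pass",
    "envelope",
    "band_velocity_correlation",
    "cross_frequency_coupling",
    "CFCProfile",
]


def cutoff_to_sigma(f: float) -> float:
    """Gaussian σ (s) whose nominal cutoff frequency is ``f`` Hz."""
    return 1.0 / (2.0 * np.pi * f)


def sigma_to_cutoff(sigma: float) -> float:
    return 1.0 / (2.0 * np.pi * sigma)


@dataclass(frozen=True)
class BandSpec:
    """One subtractive-Gaussian band.

    ``sigma_highpass`` is the σ of the first (subtracted) smoothing stage,
    ``sigma_lowpass`` the σ of the final smoothing stage.  The band's
    nominal center frequency is the low-pass stage cutoff 1/(2πσlp).
    """

    sigma_highpass: float
    sigma_lowpass: float

    def __post_init__(self) -> None:
        if not (self.sigma_highpass > self.sigma_lowpass > 0):
            raise InvalidConfigError("need sigma_highpass > sigma_lowpass > 0")

    @property
    def center_freq(self) -> float:
        return sigma_to_cutoff(self.sigma_lowpass)

    @classmethod
    def from_center(cls, f: float, ratio: float = 4.0) -> "BandSpec":
        """Band centered at ``f`` Hz with the default stage-σ ratio."""
        slp = cutoff_to_sigma(f)
        return cls(sigma_highpass=ratio * slp, sigma_lowpass=slp)


_SIGMA_HP = (0.057, 0.14, 0.28, 0.57, 1.4, 2.8, 5.7)
_SIGMA_LP = (0.014, 0.035, 0.071, 0.14, 0.35, 0.71, 1.4)

#: seven standard bands, highest center frequency (11 Hz) first
DEFAULT_BANDS: tuple[BandSpec, ...] = tuple(
    BandSpec(hp, lp) for hp, lp in zip(_SIGMA_HP, _SIGMA_LP)
)

#: the named "low-pass" band: 0.22 Hz low-pass with 0.057 Hz high-pass stage
LOW_PASS_BAND = BandSpec(sigma_highpass=2.8, sigma_lowpass=0.71)


def gaussian_smooth(x: np.ndarray, sigma: float, dt: float) -> np.ndarray:
    """Gaussian smoothing with reflection padding, σ given in seconds."""
    x = np.asarray(x, dtype=float)
    sigma_bins = sigma / dt
    if sigma_bins < 1.0:
        # below one sample the kernel degenerates to the identity
        raise InvalidConfigError(
            f"sigma = {sigma} s is shorter than one sample at dt = {dt} s"
        )
    return gaussian_filter1d(x, sigma_bins, axis=-1, mode="reflect", truncate=4.0)


def high_pass(x: np.ndarray, sigma: float, dt: float) -> np.ndarray:
    """Subtractive Gaussian high-pass: x − G_σ(x)."""
    return np.asarray(x, dtype=float) - gaussian_smooth(x, sigma, dt)


def band_pass(x: np.ndarray, band: BandSpec, dt: float) -> np.ndarray:
    """G_σlp applied to the σhp-high-passed signal."""
    return gaussian_smooth(high_pass(x, band.sigma_highpass, dt), band.sigma_lowpass, dt)


def envelope(filtered: np.ndarray, dt: float | None = None, smooth_freq: float | None = None) -> np.ndarray:
    """Rectified amplitude of a filtered signal, optionally re-smoothed.

    ``smooth_freq`` (Hz) applies a Gaussian of σ = 1/(2π f) to the rectified
    signal; requires ``dt``.
    """
    env = np.abs(np.asarray(filtered, dtype=float))
    if smooth_freq is not None:
        if dt is None:
            raise InvalidConfigError("dt is required when smooth_freq is given")
        env = gaussian_smooth(env, cutoff_to_sigma(smooth_freq), dt)
    return env


def _lagged_pearson(a: np.ndarray, b: np.ndarray, max_lag_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r between a(t + lag) and b(t) for integer lags.

    Negative lag means ``a`` precedes ``b``.  Returns (lags_bins, r).
    """
    n = a.size
    lags = np.arange(-max_lag_bins, max_lag_bins + 1)
    r = np.empty(lags.size)
    for i, k in enumerate(lags):
        if k >= 0:
            aa, bb = a[k:], b[: n - k]
        else:
            aa, bb = a[: n + k], b[-k:]
        sa, sb = aa.std(), bb.std()
        r[i] = np.nan if sa == 0 or sb == 0 else pearsonr(aa, bb).statistic
    return lags, r


def band_velocity_correlation(
    activities: np.ndarray,
    behavior: BehaviorTrace,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    max_lag: float = 4.0,
) -> "pd.DataFrame":
    """Peak correlation and peak lag between band envelopes and paw speed.

    Parameters
    ----------
    activities
        (units × time) array of continuous activity on the behavior grid.
    bands
        Bands to scan; envelope is averaged across units per band.
    max_lag
        Lag range scanned, seconds; negative peak lag = neural leads.

    Returns a DataFrame with one row per band: center_freq, peak_r, peak_lag_s.
    """
    import pandas as pd

    activities = np.atleast_2d(np.asarray(activities, dtype=float))
    if activities.shape[1] != behavior.n_bins:
        raise InvalidConfigError("activity and behavior must share the time grid")
    dt = behavior.dt
    speed = behavior.speed()
    max_lag_bins = int(round(max_lag / dt))
    rows = []
    for band in bands:
        env = np.abs(band_pass(activities, band, dt)).mean(axis=0)
        if env.std() == 0:
            rows.append(dict(center_freq=band.center_freq, peak_r=np.nan,
                             peak_lag_s=np.nan, flag="zero-variance envelope"))
            continue
        lags, r = _lagged_pearson(env, speed, max_lag_bins)
        i = int(np.nanargmax(r))
        rows.append(dict(center_freq=band.center_freq, peak_r=float(r[i]),
                         peak_lag_s=float(lags[i] * dt), flag=""))
    return pd.DataFrame(rows)


@dataclass
class CFCProfile:
    """Phase-dependent amplitude modulation (cross-frequency coupling).

    16 evenly divided phase bins of the slow band (−π…π, bin centers) and
    the mean fast-band amplitude within each bin.
    """

    phase_centers: np.ndarray
    amplitude: np.ndarray

    @property
    def peak_bin(self) -> int:
        return int(np.argmax(self.amplitude))

    @property
    def peak_phase(self) -> float:
        return float(self.phase_centers[self.peak_bin])


def cross_frequency_coupling(
    signal: np.ndarray,
    dt: float,
    slow_freq: float = 0.1,
    fast_freq: float = 3.0,
    n_bins: int = 16,
    amp_smooth_freq: float = 1.5,
) -> CFCProfile:
    """Amplitude of the fast band as a function of the slow band's phase.

    The slow-band phase comes from the Hilbert transform of the band-passed
    signal; the fast-band amplitude is the rectified band-passed signal
    smoothed at ``amp_smooth_freq`` (1.5 Hz by default).
    """
    signal = np.asarray(signal, dtype=float)
    min_len = 10.0 / slow_freq
    if signal.size * dt < min_len:
        raise InvalidConfigError(
            f"need ≥ 10 slow cycles ({min_len:.0f} s at {slow_freq} Hz), "
            f"got {signal.size * dt:.0f} s"
        )
    slow = band_pass(signal, BandSpec.from_center(slow_freq), dt)
    phase = np.angle(hilbert(slow))
    fast = band_pass(signal, BandSpec.from_center(fast_freq), dt)
    amp = envelope(fast, dt=dt, smooth_freq=amp_smooth_freq)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    mean_amp = np.array(
        [amp[idx == b].mean() if np.any(idx == b) else 0.0 for b in range(n_bins)]
    )
    centers = 0.5 * (edges[:-1] + edges[1:])
    return CFCProfile(phase_centers=centers, amplitude=mean_amp)
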