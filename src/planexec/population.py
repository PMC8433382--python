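"""Population-vector correlations and their decay time constants.

Per-unit activity is binned at 10 ms, z-scored, and each time-bin column
of the resulting unit × time matrix is demeaned and scaled to unit
Euclidean norm so that a scalar product between two columns is a Pearson
correlation between population vectors.  A global "freezing" mode p —
population activity shared across behavioral states — is projected out of
every column (a_t − p·(a_t·p)).

Trials are detected purely from behavior: the paw speed is smoothed with
a 2 s-FWHM Gaussian, each time point is divided by the value 2 s earlier,
and ratio maxima above 2 mark trial centers (quiescence followed by
movement).  A trial spans ±8 s around its center (1601 bins of 10 ms).
Within-trial correlation matrices are averaged across trials, and the
decay of correlation with temporal distance from a reference bin is fit
with A·exp(−Δ/τ); τ is the population-correlation time constant.  The
reciprocal of τ is the frequency at which a first-order low-pass with
that time constant attenuates amplitude to 1/√(1+4π²) ≈ 16 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .core import BehaviorTrace, InvalidConfigError, Session
from .filtering import gaussian_smooth
from .modulation import instantaneous_rate

__all__ = [
    "PopulationMatrix",
    "TrialSet",
    "DecayFit",
    "preprocess_population",
    "detect_trials",
    "trial_correlation_matrix",
    "fit_decay",
    "decay_timecourse",
    "behavioral_frequency",
]

TRIAL_HALF_WINDOW = 8.0     # s → 1601 bins of 10 ms per trial
TRIAL_RATIO = 2.0           # speed-ratio threshold defining a trial center
TRIAL_FILTER_FWHM = 2.0     # s, Gaussian FWHM for the speed smoothing
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
TAU_BOUNDS = (0.01, 20.0)   # s
AMP_BOUNDS = (0.0, 1.5)


@dataclass
class PopulationMatrix:
    """Normalized unit × time-bin activity with the removed global mode."""

    matrix: np.ndarray            # (units × bins) after all normalization
    dt: float
    global_mode: np.ndarray | None = None   # unit vector p, None if not removed
    unit_index: np.ndarray | None = None    # session unit indices kept
    excluded: list[int] = field(default_factory=list)  # silent units dropped

    @property
    def n_units(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]


def _column_normalize(m: np.ndarray) -> np.ndarray:
    m = m - m.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(m, axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norms > 0, m / norms, 0.0)
    return out


def preprocess_population(
    session: Session,
    dt: float = 0.01,
    rate_sigma: float = 0.05,
    remove_global_mode: bool = True,
    quiescent_quantile: float = 0.1,
) -> PopulationMatrix:
    """Build the normalized population matrix of a session.

    Steps: per-unit z-score of the 10 ms-binned smoothed rate → per-column
    demean + unit-norm → optional removal of the global quiescence mode p.
    With only a single task available, p is estimated as the normalized
    mean population vector over the lowest-decile speed epochs, which
    captures the same low-arousal global activity as the cross-task
    correlation used with paired recordings.

    Silent units (zero rate SD) are excluded and reported.
    """
    if session.n_units < 2:
        raise InvalidConfigError("population analysis needs ≥ 2 units")
    duration = session.duration
    rates = np.stack([
        instantaneous_rate(u, duration, dt=dt, sigma=rate_sigma)
        for u in session.units
    ])
    sds = rates.std(axis=1)
    keep = sds > 0
    excluded = [int(i) for i in np.flatnonzero(~keep)]
    rates = rates[keep]
    if rates.shape[0] < 2:
        raise InvalidConfigError("fewer than 2 active units after exclusion")
    z = (rates - rates.mean(axis=1, keepdims=True)) / rates.std(axis=1, keepdims=True)
    m = _column_normalize(z)

    p = None
    if remove_global_mode:
        speed = session.behavior.speed()
        n = min(speed.size, m.shape[1])
        thresh = np.quantile(speed[:n], quiescent_quantile)
        quiet = np.flatnonzero(speed[:n] <= thresh)
        p = m[:, quiet].mean(axis=1)
        norm = np.linalg.norm(p)
        if norm > 0:
            p = p / norm
            m = m - np.outer(p, p @ m)
        else:
            p = None
    return PopulationMatrix(matrix=m, dt=dt, global_mode=p,
                            unit_index=np.flatnonzero(keep), excluded=excluded)


@dataclass
class TrialSet:
    """Velocity-ratio-defined trial centers with a ±8 s analysis window."""

    centers: np.ndarray          # s
    dt: float = 0.01
    half_window: float = TRIAL_HALF_WINDOW

    @property
    def n_trials(self) -> int:
        return self.centers.size

    @property
    def bins_per_trial(self) -> int:
        return 2 * int(round(self.half_window / self.dt)) + 1


def detect_trials(behavior: BehaviorTrace, ratio_delay: float = 2.0) -> TrialSet:
    """Find quiescence→movement transitions from the smoothed paw speed.

    A trial center is a local maximum of the ratio between the 2 s-FWHM
    smoothed speed and its value ``ratio_delay`` seconds earlier, provided
    the ratio exceeds 2.  Centers whose ±8 s window leaves the session are
    dropped.  An empty TrialSet is a valid result.
    """
    if behavior.duration <= 2 * TRIAL_HALF_WINDOW:
        raise InvalidConfigError("session must be longer than 16 s")
    dt = behavior.dt
    smoothed = gaussian_smooth(behavior.speed(), TRIAL_FILTER_FWHM * FWHM_TO_SIGMA, dt)
    k = int(round(ratio_delay / dt))
    eps = 1e-12
    ratio = smoothed[k:] / np.maximum(smoothed[:-k], eps)
    above = ratio > TRIAL_RATIO
    local_max = np.zeros_like(above)
    local_max[1:-1] = (ratio[1:-1] >= ratio[:-2]) & (ratio[1:-1] > ratio[2:])
    cand = np.flatnonzero(above & local_max) + k
    w = int(round(TRIAL_HALF_WINDOW / dt))
    n = behavior.n_bins
    cand = cand[(cand >= w) & (cand < n - w)]
    return TrialSet(centers=cand * dt, dt=dt)


def trial_correlation_matrix(pop: PopulationMatrix, trials: TrialSet) -> np.ndarray:
    """Mean within-trial correlation matrix (bins_per_trial square).

    Because columns are demeaned and unit-normed, the scalar-product matrix
    of a trial's columns is its Pearson-correlation matrix; matrices are
    averaged across trials.
    """
    if trials.n_trials == 0:
        raise InvalidConfigError("no trials to correlate")
    w = int(round(trials.half_window / pop.dt))
    size = 2 * w + 1
    acc = np.zeros((size, size))
    used = 0
    for c in trials.centers:
        ci = int(round(c / pop.dt))
        if ci - w < 0 or ci + w + 1 > pop.n_bins:
            continue
        a = pop.matrix[:, ci - w:ci + w + 1]
        acc += a.T @ a
        used += 1
    if used == 0:
        raise InvalidConfigError("no trial window fits in the population matrix")
    return acc / used


@dataclass
class DecayFit:
    """Exponential decay fit C(Δ) = A·exp(−Δ/τ) of the correlation."""

    tau: float
    amplitude: float
    reference_time: float      # s within the trial window (0 = center)
    residual: float

    @property
    def cutoff_frequency(self) -> float:
        """Frequency at which a first-order low-pass with this τ attenuates
        amplitude to 1/√(1+4π²) ≈ 16 %."""
        return 1.0 / self.tau


def _decay_profile(matrix: np.ndarray, ref: int, max_delta_bins: int | None,
                   dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Correlation vs |Δ| from the reference bin, two-sided averaged."""
    row = matrix[ref]
    n = row.size
    dmax = n - 1 if max_delta_bins is None else min(max_delta_bins, n - 1)
    deltas = np.arange(1, dmax + 1)
    vals = np.full(deltas.size, np.nan)
    for i, d in enumerate(deltas):
        pair = []
        if ref - d >= 0:
            pair.append(row[ref - d])
        if ref + d < n:
            pair.append(row[ref + d])
        if pair:
            vals[i] = np.mean(pair)
    ok = np.isfinite(vals)
    return deltas[ok] * dt, vals[ok]


def fit_decay(
    matrix: np.ndarray,
    reference_bin: int,
    dt: float = 0.01,
    max_delta: float | None = None,
) -> DecayFit:
    """Fit A·exp(−Δ/τ) to the correlation around one reference bin.

    Least squares (Gaussian cost) with τ ∈ [0.01, 20] s, A ∈ [0, 1.5]; τ is
    initialized at the distance where the correlation first drops below
    A₀·e^(−1).  ``max_delta`` restricts the fitted range (s), which keeps the
    estimate local when τ varies across the trial.
    """
    max_delta_bins = None if max_delta is None else int(round(max_delta / dt))
    x, y = _decay_profile(matrix, reference_bin, max_delta_bins, dt)
    if x.size < 10:
        raise InvalidConfigError("need ≥ 10 distinct distance bins for the fit")
    if np.all(y <= 0):
        raise InvalidConfigError("non-positive correlations everywhere; fit failed")
    a0 = float(np.clip(y[0], 0.05, AMP_BOUNDS[1]))
    below = np.flatnonzero(y < a0 * np.exp(-1.0))
    tau0 = float(x[below[0]]) if below.size else float(x[-1] / 2)
    tau0 = float(np.clip(tau0, *TAU_BOUNDS))
    popt, _ = curve_fit(
        lambda d, A, tau: A * np.exp(-d / tau),
        x, y, p0=[a0, tau0],
        bounds=([AMP_BOUNDS[0], TAU_BOUNDS[0]], [AMP_BOUNDS[1], TAU_BOUNDS[1]]),
        maxfev=10000,
    )
    amp, tau = float(popt[0]), float(popt[1])
    resid = float(np.sqrt(np.mean((y - amp * np.exp(-x / tau)) ** 2)))
    center = (matrix.shape[0] - 1) // 2
    return DecayFit(tau=tau, amplitude=amp,
                    reference_time=(reference_bin - center) * dt, residual=resid)


def decay_timecourse(
    matrix: np.ndarray,
    dt: float = 0.01,
    step: float = 0.2,
    max_delta: float = 2.0,
) -> "pd.DataFrame":
    """τ at reference bins across the trial, plus premove/move summaries.

    Fits are evaluated every ``step`` seconds with a local ``max_delta``
    window.  Returns a DataFrame (time_s, tau_s, amplitude, residual) with
    attrs ``tau_premove`` (τ at −1 s), ``tau_move`` (τ at +1 s) and
    ``tau_median``.
    """
    import pandas as pd

    n = matrix.shape[0]
    center = (n - 1) // 2
    stride = max(1, int(round(step / dt)))
    margin = int(round(max_delta / dt))
    refs = np.arange(margin, n - margin, stride)
    rows = []
    for r in refs:
        try:
            f = fit_decay(matrix, int(r), dt=dt, max_delta=max_delta)
            rows.append(dict(time_s=f.reference_time, tau_s=f.tau,
                             amplitude=f.amplitude, residual=f.residual))
        except (InvalidConfigError, RuntimeError):
            rows.append(dict(time_s=(r - center) * dt, tau_s=np.nan,
                             amplitude=np.nan, residual=np.nan))
    df = pd.DataFrame(rows)

    def tau_at(t: float) -> float:
        try:
            return fit_decay(matrix, center + int(round(t / dt)), dt=dt,
                             max_delta=max_delta).tau
        except (InvalidConfigError, RuntimeError):
            return float("nan")

    df.attrs["tau_premove"] = tau_at(-1.0)
    df.attrs["tau_move"] = tau_at(1.0)
    df.attrs["tau_median"] = float(np.nanmedian(df["tau_s"]))
    return df


def behavioral_frequency(
    behavior: BehaviorTrace,
    candidate_freqs: np.ndarray | None = None,
) -> float:
    """Smallest low-pass cutoff that reconstructs the speed within tracking noise.

    The maximum behavioral frequency at which the trace carries real signal:
    the lowest Gaussian low-pass cutoff (Hz) whose reconstruction RMS error
    stays within the tracking-noise SD.  Searched over the standard band
    centers by default.  This is an interpretation of a verbally specified
    estimator, not a literal published formula.
    """
    from .filtering import DEFAULT_BANDS, cutoff_to_sigma

    if candidate_freqs is None:
        candidate_freqs = np.array(sorted(b.center_freq for b in DEFAULT_BANDS))
    speed = behavior.speed()
    for f in candidate_freqs:
        rec = gaussian_smooth(speed, cutoff_to_sigma(float(f)), behavior.dt)
        err = float(np.sqrt(np.mean((speed - rec) ** 2)))
        if err <= behavior.tracking_noise_sd:
            return float(f)
    return float(candidate_freqs[-1])
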