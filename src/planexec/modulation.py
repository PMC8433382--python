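"""Activity-weighted distributions (AWD) and velocity-modulation metrics.

The AWD generalizes the spike-triggered average: at each temporal lag
(−4…4 s in 10 ms steps) the behavioral variable (paw speed by default) is
binned into 10 equal-width bins and each bin holds the *mean continuous
activity* observed when the behavior sat in that bin.  Because each bin
keeps its own mean, monotonic nonlinear tuning (e.g. exponentially
increasing rates) is captured where a linear average would wash it out.

Sign convention (movement-referenced lags): the value at lag l pairs
activity(t + l) with behavior(t), so a unit whose firing *precedes* the
movement — planning-like activity — peaks at negative lags, and a unit
driven by sensory feedback peaks at positive lags.

Per-lag modulation is the mean |AWD − baseline| across bins, with the
baseline taken per bin from the 3–4 s lags where units are no longer
behavior-locked.  From the modulation curve come the headline per-unit
metrics: peak, duration (width of the ≥ 80 %-of-peak region), lag (center
of that region), a modulated/not-modulated call (normalized peak > 10),
and a planning-vs-sensory index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import BehaviorTrace, InvalidConfigError, SortedUnit
from .filtering import gaussian_smooth

__all__ = [
    "AWDTable",
    "ModulationProfile",
    "instantaneous_rate",
    "compute_awd",
    "modulation_metrics",
    "planning_sensory_index",
    "bootstrap_duration",
]

MAX_LAG = 4.0          # s, AWD lag range is [−MAX_LAG, MAX_LAG]
N_BINS = 10            # equal-width behavior bins
RATE_SIGMA = 0.05      # s, Gaussian SD of the instantaneous-rate smoothing
PEAK_FRACTION = 0.8    # duration = width of the ≥ 80 %-of-peak region
MODULATED_THRESHOLD = 10.0   # normalized-modulation criterion (a.u.)


def instantaneous_rate(
    unit: SortedUnit | np.ndarray,
    duration: float,
    dt: float = 0.01,
    sigma: float = RATE_SIGMA,
) -> np.ndarray:
    """Binned spike counts / dt smoothed with a Gaussian kernel (SD 50 ms).

    Returns a nonnegative trace on the 10 ms grid whose integral is ≈ the
    spike count.  An empty train gives an all-zero trace.
    """
    times = unit.spike_times if isinstance(unit, SortedUnit) else np.asarray(unit, float)
    n_bins = int(round(duration / dt))
    counts, _ = np.histogram(times, bins=n_bins, range=(0.0, n_bins * dt))
    rate = counts.astype(float) / dt
    if sigma > 0:
        rate = gaussian_smooth(rate, sigma, dt)
    return rate


@dataclass
class AWDTable:
    """Lag × behavior-bin lookup of mean activity.

    ``values[i, b]`` is the mean activity at lag ``lags[i]`` for behavior
    bin ``b``; ``counts`` holds the number of samples behind each cell
    (0 ⇒ the cell is NaN and excluded from all means).
    """

    lags: np.ndarray            # (L,) seconds
    bin_edges: np.ndarray       # (N_BINS + 1,)
    values: np.ndarray          # (L, N_BINS), NaN where empty
    counts: np.ndarray          # (L, N_BINS) int
    dt: float = 0.01

    @property
    def n_lags(self) -> int:
        return self.lags.size

    def baseline(self) -> np.ndarray:
        """Per-bin mean activity over the 3–4 s lags."""
        sel = (self.lags >= MAX_LAG - 1.0) & (self.lags <= MAX_LAG)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values[sel], axis=0)

    def modulation(self) -> np.ndarray:
        """Per-lag mean |AWD − baseline| across bins (empty cells excluded)."""
        diff = np.abs(self.values - self.baseline()[None, :])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(diff, axis=1)


def _awd_sums(
    activity: np.ndarray,
    bin_idx: np.ndarray,
    lag_bins: np.ndarray,
    start: int = 0,
    stop: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate per-(lag, bin) activity sums and counts.

    Pairs activity[t + k] with the behavior bin at t, restricting t to
    [start, stop) so the same routine serves full-session and per-segment
    tables.  Pairs whose activity index falls outside the session are
    dropped.
    """
    n = activity.size
    stop = n if stop is None else stop
    sums = np.zeros((lag_bins.size, N_BINS))
    counts = np.zeros((lag_bins.size, N_BINS), dtype=np.int64)
    for i, k in enumerate(lag_bins):
        lo = max(start, -k)
        hi = min(stop, n - k)
        if hi <= lo:
            continue
        b = bin_idx[lo:hi]
        a = activity[lo + k:hi + k]
        counts[i] = np.bincount(b, minlength=N_BINS)
        sums[i] = np.bincount(b, weights=a, minlength=N_BINS)
    return sums, counts


def _behavior_bins(variable: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vmin, vmax = float(np.min(variable)), float(np.max(variable))
    if vmax <= vmin:
        raise InvalidConfigError(
            "behavioral variable is constant; AWD binning is degenerate"
        )
    edges = np.linspace(vmin, vmax, N_BINS + 1)
    idx = np.clip(((variable - vmin) / (vmax - vmin) * N_BINS).astype(int), 0, N_BINS - 1)
    return edges, idx


def compute_awd(
    activity: np.ndarray,
    behavior: BehaviorTrace,
    variable: np.ndarray | None = None,
    max_lag: float = MAX_LAG,
) -> AWDTable:
    """Activity-weighted distribution of a behavioral variable.

    Parameters
    ----------
    activity
        Continuous activity on the behavior grid (e.g. the 50 ms-smoothed
        instantaneous rate).
    variable
        Behavioral variable to bin; defaults to paw speed.  Pass e.g.
        ``behavior.vx`` or a position trace for the per-axis variants.
    """
    activity = np.asarray(activity, dtype=float)
    if activity.shape != behavior.vx.shape:
        raise InvalidConfigError("activity and behavior must share the 10 ms grid")
    variable = behavior.speed() if variable is None else np.asarray(variable, float)
    dt = behavior.dt
    k_max = int(round(max_lag / dt))
    lag_bins = np.arange(-k_max, k_max + 1)
    edges, idx = _behavior_bins(variable)
    sums, counts = _awd_sums(activity, idx, lag_bins)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return AWDTable(lags=lag_bins * dt, bin_edges=edges, values=values,
                    counts=counts, dt=dt)


@dataclass
class ModulationProfile:
    """Per-unit summary of the velocity-modulation curve."""

    lags: np.ndarray
    modulation: np.ndarray
    normalized: np.ndarray
    peak_value: float
    duration: float          # s, width of the ≥ 80 %-of-peak region
    lag: float               # s, midpoint of that region
    modulated: bool
    capped: bool = False     # True when the region touched the ±4 s border
    flags: list[str] = field(default_factory=list)


def modulation_metrics(awd: AWDTable) -> ModulationProfile:
    """Peak / duration / lag / modulated-call from an AWD table.

    The modulation is traced backward and forward from its global peak
    until it drops below 80 % of the peak; the duration is the time between
    those two crossings and the lag is their midpoint (more robust than the
    peak position when the curve plateaus).  The modulated criterion
    normalizes the curve by the mean and SD of its two extreme-lag stretches
    (−4…−3 s and 3…4 s) and asks for a peak above 10.
    """
    mod = awd.modulation()
    lags = awd.lags
    finite = np.isfinite(mod)
    if not finite.any() or np.nanmax(mod) <= 0:
        z = np.zeros_like(mod)
        return ModulationProfile(lags=lags, modulation=mod, normalized=z,
                                 peak_value=0.0, duration=2 * MAX_LAG, lag=0.0,
                                 modulated=False, capped=True,
                                 flags=["flat modulation curve"])
    peak_i = int(np.nanargmax(mod))
    peak = float(mod[peak_i])
    thr = PEAK_FRACTION * peak

    lo = peak_i
    while lo > 0 and finite[lo - 1] and mod[lo - 1] >= thr:
        lo -= 1
    hi = peak_i
    while hi < mod.size - 1 and finite[hi + 1] and mod[hi + 1] >= thr:
        hi += 1
    capped = lo == 0 or hi == mod.size - 1
    duration = float(lags[hi] - lags[lo])
    center = float(0.5 * (lags[hi] + lags[lo]))

    ext = (np.abs(lags) >= MAX_LAG - 1.0)
    ext_vals = mod[ext & finite]
    sd = ext_vals.std()
    if sd > 0:
        z = (mod - ext_vals.mean()) / sd
    else:
        z = np.zeros_like(mod)
    modulated = bool(np.nanmax(z) > MODULATED_THRESHOLD)

    flags = ["duration capped at lag range"] if capped else []
    return ModulationProfile(lags=lags, modulation=mod, normalized=z,
                             peak_value=peak, duration=duration, lag=center,
                             modulated=modulated, capped=capped, flags=flags)


def planning_sensory_index(profile: ModulationProfile) -> float:
    """Normalized planning-vs-sensory contrast, in percent.

    100·(P − S)/(P + S) with P the summed modulation over the planning
    window (lags −1.1 to −0.1 s) and S the summed modulation over the
    sensory-integration window (0 to 1 s).  +100 ⇒ purely movement-leading,
    −100 ⇒ purely movement-following; NaN when both windows are empty.
    """
    lags, mod = profile.lags, profile.modulation
    p_sel = (lags >= -1.1) & (lags <= -0.1)
    s_sel = (lags >= 0.0) & (lags <= 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = float(np.nansum(mod[p_sel]))
        s = float(np.nansum(mod[s_sel]))
    if p + s == 0:
        profile.flags.append("planning_sensory_index undefined (P + S = 0)")
        return float("nan")
    return 100.0 * (p - s) / (p + s)


def bootstrap_duration(
    activity: np.ndarray,
    behavior: BehaviorTrace,
    n_segments: int = 100,
    n_reps: int = 100,
    seed: int = 0,
    max_lag: float = MAX_LAG,
) -> tuple[float, np.ndarray]:
    """Segment-bootstrap SD of the modulation duration.

    The session is cut into ``n_segments`` contiguous equal-size segments
    and the AWD sums/counts are accumulated per segment; each bootstrap
    repetition resamples segments with replacement, pools their sums and
    counts into one AWD (a count-weighted mean of per-segment tables) and
    recomputes the duration.  Returns (SD, per-rep durations).
    """
    if n_segments < 2:
        raise InvalidConfigError("n_segments must be ≥ 2")
    if n_reps < 10:
        raise InvalidConfigError("n_reps must be ≥ 10")
    activity = np.asarray(activity, dtype=float)
    n = activity.size
    dt = behavior.dt
    if n * dt / n_segments < 10.0:
        warnings.warn(
            "segments are shorter than 10 s; bootstrap durations may be noisy",
            stacklevel=2,
        )
    k_max = int(round(max_lag / dt))
    lag_bins = np.arange(-k_max, k_max + 1)
    edges, idx = _behavior_bins(behavior.speed())
    bounds = np.linspace(0, n, n_segments + 1).astype(int)
    seg_sums = np.empty((n_segments, lag_bins.size, N_BINS))
    seg_counts = np.empty((n_segments, lag_bins.size, N_BINS), dtype=np.int64)
    for s in range(n_segments):
        seg_sums[s], seg_counts[s] = _awd_sums(
            activity, idx, lag_bins, start=bounds[s], stop=bounds[s + 1]
        )
    rng = np.random.default_rng(seed)
    durations = np.empty(n_reps)
    for r in range(n_reps):
        pick = rng.integers(0, n_segments, size=n_segments)
        sums = seg_sums[pick].sum(axis=0)
        counts = seg_counts[pick].sum(axis=0)
        with np.errstate(invalid="ignore"):
            values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        table = AWDTable(lags=lag_bins * dt, bin_edges=edges, values=values,
                         counts=counts, dt=dt)
        durations[r] = modulation_metrics(table).duration
    return float(durations.std()), durations
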