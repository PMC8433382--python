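"""Ground-truth session generator.

Real sessions of this kind (freely moving rats doing minimally repetitive
paw movements with simultaneous S1/M1/M2 single-electrode recordings) are
not publicly deposited, so every downstream analysis is validated against
synthetic sessions with known structure:

* behavior: alternating quiescent / active epochs (two-state semi-Markov
  gate) carrying sub-movement speed oscillations with a spectral peak near
  4–5 Hz, a slowly drifting movement direction, and additive white tracking
  noise (0.79 cm/s per axis by default);
* units: inhomogeneous Poisson spiking whose rate follows the paw speed at
  a controllable lag (negative = unit leads the movement) through a
  Gaussian temporal blur of controllable width (modulation_sigma) and a
  linear or exponential link;
* optionally a raw 30 kHz voltage trace with embedded spike waveforms for
  the sorter.

All randomness flows through one integer seed per operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import welch

from .core import BehaviorTrace, InvalidConfigError, RawTrace, Session, SortedUnit
from .filtering import gaussian_smooth

__all__ = [
    "BehaviorConfig",
    "UnitSpec",
    "generate_behavior",
    "generate_session",
    "generate_raw_trace",
    "unit_rate",
    "make_templates",
    "generate_ar1_population",
    "speed_spectrum_peak",
]

SNIPPET_LEN = 76       # −0.5 … +2 ms at 30 kHz
PEAK_SAMPLE = 15       # 0-based index of the negative peak (0.5 ms × 30 kHz)
MAX_RATE_HZ = 500.0    # physiological ceiling; above this the config is invalid


@dataclass
class BehaviorConfig:
    """Parameters of the behavior generator.

    The defaults emulate the locomotor condition: trains of brief velocity
    pulses (sub-movements) recurring at 4.7 Hz during movement bouts of a
    few seconds, separated by shorter quiescent pauses, with 0.79 cm/s
    tracking noise per axis.  Each pulse has its own movement direction,
    drifting from pulse to pulse, so the velocity components carry little
    very-low-frequency power even though bouts are seconds long.
    """

    duration: float = 600.0
    dt: float = 0.01
    submovement_freq: float = 4.7      # Hz, pulse rate = spectral peak of speed
    submovement_jitter: float = 0.2    # relative SD of the inter-pulse interval
    amplitude: float = 8.0             # cm/s, peak speed of a typical pulse
    amplitude_jitter: float = 0.4      # relative SD of per-pulse amplitudes
    active_dwell: float = 4.0          # s, mean active-epoch duration
    quiet_dwell: float = 2.0           # s, mean quiescent-epoch duration
    axis_drift: float = 0.3            # rad SD of the per-pulse movement-axis drift
    return_prob: float = 0.9           # probability that a pulse reverses the last one
    direction_jitter: float = 0.3      # rad SD of per-pulse heading jitter
    tracking_noise_sd: float = 0.79    # cm/s per velocity axis


def _semi_markov_gate(n: int, dt: float, active_dwell: float, quiet_dwell: float,
                      rng: np.random.Generator) -> np.ndarray:
    """0/1 movement gate with gamma-distributed dwell times (shape 2)."""
    gate = np.zeros(n)
    t = 0
    state = rng.random() < active_dwell / (active_dwell + quiet_dwell)
    while t < n:
        mean = active_dwell if state else quiet_dwell
        dwell = max(1, int(round(rng.gamma(2.0, mean / 2.0) / dt)))
        if state:
            gate[t:t + dwell] = 1.0
        t += dwell
        state = not state
    return gate


def generate_behavior(config: BehaviorConfig | None = None, seed: int = 0) -> BehaviorTrace:
    """Generate a non-repetitive 2-D paw-velocity trace.

    Sub-movements are Gaussian speed pulses (σ = one sixth of the pulse
    period) on a jittered grid at the sub-movement frequency, scaled by the
    quiescence/movement gate and a per-pulse amplitude factor.  Pulses
    shuttle back and forth along a slowly rotating movement axis: with
    probability ``return_prob`` a pulse reverses the previous one (the paw
    workspace is bounded, so outward strokes are followed by return
    strokes), which concentrates velocity-component power near half the
    pulse rate and removes spurious very-low-frequency drift.  The
    quasi-periodic pulse train keeps the spectral peak of the *speed* trace
    at the pulse rate itself.  White tracking noise is added per axis.
    """
    config = config or BehaviorConfig()
    if config.duration <= 0 or config.dt <= 0:
        raise InvalidConfigError("duration and dt must be positive")
    if config.duration < 60.0:
        raise InvalidConfigError("duration must be at least 60 s")
    rng = np.random.default_rng(seed)
    n = int(round(config.duration / config.dt))
    dt = config.dt

    gate = _semi_markov_gate(n, dt, config.active_dwell, config.quiet_dwell, rng)
    gate = gaussian_smooth(gate, 0.3, dt)

    vx = np.zeros(n)
    vy = np.zeros(n)
    if config.amplitude > 0:
        period = 1.0 / config.submovement_freq
        sigma_p = period / 6.0
        half = int(round(3.0 * sigma_p / dt))
        kernel = np.exp(
            -0.5 * ((np.arange(-half, half + 1) * dt) / sigma_p) ** 2
        )
        axis = 2.0 * np.pi * rng.random()
        sign = 1.0
        t = rng.random() * period
        while t < config.duration:
            c = int(round(t / dt))
            amp = config.amplitude * gate[min(c, n - 1)] * max(
                0.0, 1.0 + config.amplitude_jitter * rng.standard_normal()
            )
            theta = axis + config.direction_jitter * rng.standard_normal()
            lo, hi = max(0, c - half), min(n, c + half + 1)
            if hi > lo and amp > 0:
                seg = kernel[lo - (c - half):hi - (c - half)]
                vx[lo:hi] += sign * amp * np.cos(theta) * seg
                vy[lo:hi] += sign * amp * np.sin(theta) * seg
            if rng.random() < config.return_prob:
                sign = -sign
            axis += config.axis_drift * rng.standard_normal()
            t += period * max(0.2, 1.0 + config.submovement_jitter * rng.standard_normal())

    vx += rng.normal(0.0, config.tracking_noise_sd, n)
    vy += rng.normal(0.0, config.tracking_noise_sd, n)
    return BehaviorTrace(vx=vx, vy=vy, dt=dt,
                         tracking_noise_sd=config.tracking_noise_sd)


def speed_spectrum_peak(behavior: BehaviorTrace, fmin: float = 0.5) -> float:
    """Frequency (Hz) of the Welch-PSD peak of the speed trace above fmin.

    Frequencies below ``fmin`` are excluded because the quiescence/movement
    alternation concentrates power near DC; the sub-movement peak lives
    above it.
    """
    speed = behavior.speed()
    nperseg = min(speed.size, int(round(20.0 / behavior.dt)))
    f, pxx = welch(speed - speed.mean(), fs=1.0 / behavior.dt, nperseg=nperseg)
    sel = f >= fmin
    return float(f[sel][np.argmax(pxx[sel])])


@dataclass
class UnitSpec:
    """Ground truth for one synthetic unit.

    ``lag`` < 0 means the unit's activity leads the movement (planning-like);
    ``modulation_sigma`` is the SD of the Gaussian blur applied to the speed
    drive and controls the recovered modulation duration.
    """

    lag: float = 0.0                # s
    modulation_sigma: float = 0.1   # s, must be > 0
    gain: float = 2.0               # Hz per (cm/s)
    baseline_rate: float = 2.0      # Hz
    area: str = "M1"
    nonlinearity: str = "linear"    # or "exponential"
    exp_scale: float = 4.0          # cm/s scale of the exponential link
    drive: str = "speed"            # behavioral drive: speed, vx or vy

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise InvalidConfigError("baseline_rate must be ≥ 0")
        if not self.modulation_sigma > 0:
            raise InvalidConfigError("modulation_sigma must be > 0")
        if self.nonlinearity not in ("linear", "exponential"):
            raise InvalidConfigError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.drive not in ("speed", "vx", "vy"):
            raise InvalidConfigError(f"unknown drive {self.drive!r}")


def _shift(x: np.ndarray, k: int) -> np.ndarray:
    """x(t − k·dt) with edge-value padding; k < 0 looks into the future."""
    if k == 0:
        return x
    out = np.empty_like(x)
    if k > 0:
        out[k:] = x[:-k]
        out[:k] = x[0]
    else:
        out[:k] = x[-k:]
        out[k:] = x[-1]
    return out


def unit_rate(behavior: BehaviorTrace, spec: UnitSpec) -> np.ndarray:
    """Deterministic instantaneous rate (Hz) implied by a unit spec.

    ``drive='speed'`` models unsigned velocity tuning (the default);
    ``'vx'`` / ``'vy'`` give signed directional tuning, which the lag-based
    output-potent analysis requires.
    """
    variable = {"speed": behavior.speed(), "vx": behavior.vx, "vy": behavior.vy}[spec.drive]
    smoothed = gaussian_smooth(variable, spec.modulation_sigma, behavior.dt)
    drive = _shift(smoothed, int(round(spec.lag / behavior.dt)))
    if spec.nonlinearity == "exponential":
        drive = np.expm1(drive / spec.exp_scale)
    rate = np.maximum(0.0, spec.baseline_rate + spec.gain * drive)
    if np.any(rate > MAX_RATE_HZ):
        raise InvalidConfigError(
            f"rate exceeds {MAX_RATE_HZ} Hz; reduce gain or baseline"
        )
    return rate


def generate_session(
    behavior: BehaviorTrace,
    unit_specs: list[UnitSpec],
    seed: int = 0,
    task: str = "locomotor",
) -> Session:
    """Draw inhomogeneous-Poisson spike trains for each unit spec.

    Spike counts are Poisson per 10 ms bin with the bin's rate, and spike
    times are jittered uniformly within the bin.  Ground-truth lag /
    modulation_sigma / gain are stored in each unit's ``meta``.
    """
    if not unit_specs:
        raise InvalidConfigError("unit_specs must be non-empty")
    rng = np.random.default_rng(seed)
    dt = behavior.dt
    units = []
    for spec in unit_specs:
        rate = unit_rate(behavior, spec)
        counts = rng.poisson(rate * dt)
        idx = np.repeat(np.arange(counts.size), counts)
        times = (idx + rng.random(idx.size)) * dt
        units.append(
            SortedUnit(
                spike_times=np.sort(times),
                area=spec.area,
                unit_class="SU",
                meta=dict(
                    true_lag=spec.lag,
                    true_modulation_sigma=spec.modulation_sigma,
                    gain=spec.gain,
                    baseline_rate=spec.baseline_rate,
                    nonlinearity=spec.nonlinearity,
                ),
            )
        )
    return Session(behavior=behavior, units=units, task=task, seed=seed)


def make_templates(n_templates: int = 3, peak_amplitude: float = -80.0,
                   seed: int = 0) -> list[np.ndarray]:
    """Biphasic 76-sample spike waveforms with the trough at sample 15.

    Templates differ in trough width, rebound amplitude and rebound delay so
    that a distance-based sorter can separate them.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(SNIPPET_LEN, dtype=float)
    templates = []
    for i in range(n_templates):
        trough_w = 2.0 + 3.0 * i + rng.uniform(-0.2, 0.2)
        rebound_delay = 10.0 + 14.0 * i
        rebound_w = 6.0 + 5.0 * i
        rebound_amp = (0.2 + 0.45 * i) * abs(peak_amplitude)
        sign = 1.0 if i % 2 else -1.0
        pre_amp = sign * (0.4 + 0.15 * i) * abs(peak_amplitude)
        w = (1.0 + 0.9 * i) * peak_amplitude * np.exp(-0.5 * ((t - PEAK_SAMPLE) / trough_w) ** 2)
        w += rebound_amp * np.exp(-0.5 * ((t - PEAK_SAMPLE - rebound_delay) / rebound_w) ** 2)
        w += pre_amp * np.exp(-0.5 * ((t - PEAK_SAMPLE - 2.0 * rebound_delay) / (2.0 * rebound_w)) ** 2)
        # enforce exact trough position and a clean start
        w -= w[0]
        assert np.argmin(w) == PEAK_SAMPLE
        templates.append(w)
    return templates


def generate_raw_trace(
    templates: list[np.ndarray],
    rates: float | list[float],
    noise_sd: float,
    duration: float,
    seed: int = 0,
    fs: float = 30000.0,
) -> RawTrace:
    """Superimpose Poisson-timed template occurrences on white noise.

    Occurrences of the same template are never closer than 2 ms (enforced by
    thinning).  Ground truth (template_id, peak_time) pairs are recorded.
    """
    for tpl in templates:
        if len(tpl) != SNIPPET_LEN:
            raise InvalidConfigError(f"templates must have {SNIPPET_LEN} samples")
    if np.isscalar(rates):
        rates = [float(rates)] * len(templates)
    if len(rates) != len(templates):
        raise InvalidConfigError("need one rate per template")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    voltage = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    refractory = 0.002
    ground_truth: list[tuple[int, float]] = []
    for tid, (tpl, rate) in enumerate(zip(templates, rates)):
        if rate <= 0:
            continue
        t, times = 0.0, []
        while True:
            t += rng.exponential(1.0 / rate) + refractory
            if t >= duration:
                break
            times.append(t)
        tpl = np.asarray(tpl, dtype=float)
        for ti in times:
            p = int(round(ti * fs))
            lo, hi = p - PEAK_SAMPLE, p - PEAK_SAMPLE + SNIPPET_LEN
            if lo < 0 or hi > n:
                continue
            voltage[lo:hi] += tpl
            ground_truth.append((tid, p / fs))
    ground_truth.sort(key=lambda g: g[1])
    return RawTrace(voltage=voltage, fs=fs, ground_truth=ground_truth)


def generate_ar1_population(
    n_units: int,
    n_bins: int,
    tau: float | np.ndarray,
    dt: float = 0.01,
    seed: int = 0,
) -> np.ndarray:
    """Unit × time matrix of independent AR(1) processes with time constant τ.

    ``tau`` may be a scalar or a per-bin array (s), giving a population whose
    correlation decays as exp(−Δ/τ) locally — the ground truth for the
    population-correlation decay fit.
    """
    rng = np.random.default_rng(seed)
    tau = np.broadcast_to(np.asarray(tau, dtype=float), (n_bins,))
    if np.any(tau <= 0):
        raise InvalidConfigError("tau must be positive")
    a = np.exp(-dt / tau)
    innov_sd = np.sqrt(1.0 - a**2)
    x = np.empty((n_units, n_bins))
    x[:, 0] = rng.standard_normal(n_units)
    eps = rng.standard_normal((n_units, n_bins))
    for t in range(1, n_bins):
        x[:, t] = a[t] * x[:, t - 1] + innov_sd[t] * eps[:, t]
    return x
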