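"""Core data containers for behavior + spiking sessions.

A session pairs a uniformly sampled 2-D paw-velocity trace (10 ms grid by
default) with a list of sorted spiking units carrying cortical-area labels
(S1 / M1 / M2).  Everything downstream — velocity-modulation tables,
population matrices, kernels — is derived from these two pieces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AREAS = ("S1", "M1", "M2")

#: default tracking-noise standard deviation of the paw-velocity estimate, cm/s
TRACKING_NOISE_SD = 0.79


class InvalidConfigError(ValueError):
    """Raised when a generator or analysis configuration is inconsistent."""


@dataclass
class BehaviorTrace:
    """Uniformly sampled 2-D paw velocity (and optional position).

    Parameters
    ----------
    vx, vy
        Velocity components in cm/s, one value per time bin.
    dt
        Sampling step in seconds (default 0.01).
    t0
        Time of the first sample in seconds.
    tracking_noise_sd
        Standard deviation of the additive tracking noise on each velocity
        component, cm/s.
    """

    vx: np.ndarray
    vy: np.ndarray
    dt: float = 0.01
    t0: float = 0.0
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    tracking_noise_sd: float = TRACKING_NOISE_SD

    def __post_init__(self) -> None:
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        if self.vx.shape != self.vy.shape or self.vx.ndim != 1:
            raise InvalidConfigError("vx and vy must be 1-D arrays of equal length")
        if not self.dt > 0:
            raise InvalidConfigError("dt must be positive")
        if not (np.all(np.isfinite(self.vx)) and np.all(np.isfinite(self.vy))):
            raise InvalidConfigError("velocity values must be finite")

    @property
    def n_bins(self) -> int:
        return self.vx.size

    @property
    def duration(self) -> float:
        return self.n_bins * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_bins) * self.dt

    def speed(self) -> np.ndarray:
        """Euclidean norm of the velocity, cm/s (always ≥ 0)."""
        return np.hypot(self.vx, self.vy)


@dataclass
class SortedUnit:
    """A sorted unit: spike times plus waveform / area metadata.

    ``unit_class`` distinguishes single units (SU) from multi-units (MU);
    both enter the analyses on equal footing.
    """

    spike_times: np.ndarray
    area: str = "M1"
    unit_class: str = "MU"
    mean_waveform: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=float)
        if st.ndim != 1:
            raise InvalidConfigError("spike_times must be 1-D")
        if np.any(np.diff(st) < 0):
            st = np.sort(st)
        self.spike_times = st

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    def firing_rate(self, duration: float) -> float:
        return self.n_spikes / duration if duration > 0 else np.nan


@dataclass
class Session:
    """Container of one recording session: behavior + sorted units."""

    behavior: BehaviorTrace
    units: list[SortedUnit]
    task: str = "locomotor"
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.units) < 1:
            raise InvalidConfigError("a session needs at least one unit")
        d = self.duration
        for u in self.units:
            if u.n_spikes and (u.spike_times[0] < 0 or u.spike_times[-1] > d):
                raise InvalidConfigError("spike times must lie within [0, duration]")

    @property
    def duration(self) -> float:
        return self.behavior.duration

    @property
    def n_units(self) -> int:
        return len(self.units)

    def units_in_area(self, area: str) -> list[SortedUnit]:
        return [u for u in self.units if u.area == area]


@dataclass
class RawTrace:
    """Single-channel extracellular voltage trace at 30 kHz.

    ``ground_truth`` optionally records the (template_id, peak_time) pairs a
    synthetic generator embedded, for sorter validation.
    """

    voltage: np.ndarray
    fs: float = 30000.0
    ground_truth: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        if not np.all(np.isfinite(self.voltage)):
            raise InvalidConfigError("voltage samples must be finite")

    @property
    def duration(self) -> float:
        return self.voltage.size / self.fs
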