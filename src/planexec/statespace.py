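"""Lag-based output-null / output-potent analysis and frequency dominance.

Without an instructed-delay trial structure, planning and execution phases
are defined by the lag between paw velocity and neural activity: the
velocity tuning of each unit is the time average of anterior-posterior paw
velocity × activity at lags −1…1 s (10 ms steps), giving an N × 201
matrix.  The top-2 principal components reduce it to a 2 × 201 trajectory.
The output-potent axis is the normalized trajectory point at the execution
lag (−40 ms — the lag whose tuning correlates least with the mean tuning
over the putative planning lags −1000…−200 ms); the output-null axis is
orthogonal.  State tuning at each lag is |⟨traj, potent⟩| − |⟨traj, null⟩|.

Frequency tuning treats the trajectory's lag axis as time: the amplitude
of its > split-frequency component minus its < split-frequency component
(1.1 Hz by default).  Pooling lags by the sign of the frequency tuning and
averaging the state tuning per pool asks whether fast changes live in the
output-potent space and slow changes in the null space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import InvalidConfigError, Session
from .filtering import cutoff_to_sigma, gaussian_smooth
from .modulation import instantaneous_rate

__all__ = ["StateSpaceResult", "lag_tuning_projection", "state_vs_frequency"]

LAG_RANGE = 1.0          # s → 201 lags at 10 ms
EXECUTION_LAG = -0.04    # s, default potent-axis lag
PLANNING_WINDOW = (-1.0, -0.2)   # s, reference window for re-deriving the lag
SPLIT_FREQ = 1.1         # Hz, high/low frequency split


@dataclass
class StateSpaceResult:
    """Lag-tuning matrix, reduced trajectory and potent/null tunings."""

    lags: np.ndarray             # (201,) s
    tuning: np.ndarray           # (N × 201) velocity tuning per unit and lag
    trajectory: np.ndarray       # (2 × 201) top-2 PC projection
    potent_axis: np.ndarray      # unit 2-vector
    null_axis: np.ndarray        # unit 2-vector, ⟂ potent
    state_tuning: np.ndarray     # (201,) |potent comp| − |null comp|
    execution_lag: float
    explained_variance: np.ndarray = field(default_factory=lambda: np.zeros(2))


def lag_tuning_projection(
    session: Session,
    dt: float = 0.01,
    rate_sigma: float = 0.05,
    activities: np.ndarray | None = None,
    execution_lag: float | None = EXECUTION_LAG,
) -> StateSpaceResult:
    """Velocity-lag tuning matrix, PCA reduction and potent/null axes.

    ``execution_lag=None`` re-derives the potent lag per session as the lag
    in [−100, 0] ms whose trajectory point correlates least (in absolute
    terms) with the mean trajectory over the planning window.
    """
    if session.n_units < 3:
        raise InvalidConfigError("state-space analysis needs ≥ 3 units")
    if activities is None:
        acts = np.stack([
            instantaneous_rate(u, session.duration, dt=dt, sigma=rate_sigma)
            for u in session.units
        ])
    else:
        acts = np.atleast_2d(np.asarray(activities, dtype=float))
    sds = acts.std(axis=1, keepdims=True)
    acts = (acts - acts.mean(axis=1, keepdims=True)) / np.where(sds > 0, sds, 1.0)
    v_ap = session.behavior.vx - session.behavior.vx.mean()
    n = v_ap.size
    k_max = int(round(LAG_RANGE / dt))
    lag_bins = np.arange(-k_max, k_max + 1)
    tuning = np.empty((acts.shape[0], lag_bins.size))
    for i, k in enumerate(lag_bins):
        if k >= 0:
            tuning[:, i] = acts[:, k:] @ v_ap[: n - k] / (n - k)
        else:
            tuning[:, i] = acts[:, :k] @ v_ap[-k:] / (n + k)

    centered = tuning - tuning.mean(axis=1, keepdims=True)
    u_svd, s_svd, vt = np.linalg.svd(centered, full_matrices=False)
    if s_svd.size < 2 or s_svd[1] <= 1e-12 * max(s_svd[0], 1.0):
        raise InvalidConfigError("degenerate tuning matrix: PCA rank < 2")
    trajectory = (s_svd[:2, None] * vt[:2])         # 2 × 201
    lags = lag_bins * dt
    var = s_svd**2 / max(centered.size - 1, 1)

    if execution_lag is None:
        plan_sel = (lags >= PLANNING_WINDOW[0]) & (lags <= PLANNING_WINDOW[1])
        plan_mean = trajectory[:, plan_sel].mean(axis=1)
        cand_sel = np.flatnonzero((lags >= -0.1) & (lags <= 0.0))
        best, best_corr = cand_sel[0], np.inf
        for i in cand_sel:
            p = trajectory[:, i]
            denom = np.linalg.norm(p) * np.linalg.norm(plan_mean)
            c = abs(p @ plan_mean / denom) if denom > 0 else np.inf
            if c < best_corr:
                best, best_corr = i, c
        exec_idx = int(best)
    else:
        exec_idx = int(np.argmin(np.abs(lags - execution_lag)))
    potent = trajectory[:, exec_idx]
    norm = np.linalg.norm(potent)
    if norm == 0:
        raise InvalidConfigError("zero trajectory at the execution lag")
    potent = potent / norm
    null = np.array([-potent[1], potent[0]])
    state_tuning = np.abs(potent @ trajectory) - np.abs(null @ trajectory)
    return StateSpaceResult(
        lags=lags, tuning=tuning, trajectory=trajectory,
        potent_axis=potent, null_axis=null, state_tuning=state_tuning,
        execution_lag=float(lags[exec_idx]), explained_variance=var[:2],
    )


def state_vs_frequency(
    result: StateSpaceResult,
    split: float = SPLIT_FREQ,
    dt: float = 0.01,
) -> dict:
    """Pool lags by frequency dominance and average the state tuning.

    The reduced trajectory is filtered along its lag axis: the component
    above ``split`` Hz (trajectory − Gaussian low-pass at the split cutoff)
    versus the low-pass component.  Frequency tuning per lag is the
    Euclidean amplitude of the fast component minus that of the slow
    component; lags are pooled by its sign and the mean state tuning of
    each pool is returned.
    """
    traj = result.trajectory
    sigma = cutoff_to_sigma(split)
    if traj.shape[1] * dt < 2.0 * sigma:
        raise InvalidConfigError("trajectory shorter than twice the slow-band support")
    low = gaussian_smooth(traj, sigma, dt)
    high = traj - low
    freq_tuning = np.linalg.norm(high, axis=0) - np.linalg.norm(low, axis=0)
    high_pool = freq_tuning > 0
    low_pool = freq_tuning < 0
    out = {
        "frequency_tuning": freq_tuning,
        "n_high": int(high_pool.sum()),
        "n_low": int(low_pool.sum()),
        "state_tuning_high": float(result.state_tuning[high_pool].mean())
        if high_pool.any() else float("nan"),
        "state_tuning_low": float(result.state_tuning[low_pool].mean())
        if low_pool.any() else float("nan"),
        "flag": "",
    }
    if not high_pool.any() or not low_pool.any():
        out["flag"] = "degenerate pools: frequency tuning has one sign everywhere"
    return out
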