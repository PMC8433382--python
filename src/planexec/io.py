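"""HDF5 / CSV persistence for sessions.

Layout of a session file::

    /behavior          t0, dt attrs; vx, vy datasets (cm/s)
    /units/<k>         spike_times (s); attrs area, unit_class; optional waveform
    /meta              attrs task, seed, free-form scalars

Behavior alone can also round-trip through a plain CSV with columns
``time, vx, vy``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import BehaviorTrace, RawTrace, Session, SortedUnit


def save_session(path: str | Path, session: Session) -> None:
    with h5py.File(path, "w") as f:
        b = f.create_group("behavior")
        b.attrs["t0"] = session.behavior.t0
        b.attrs["dt"] = session.behavior.dt
        b.attrs["tracking_noise_sd"] = session.behavior.tracking_noise_sd
        b.create_dataset("vx", data=session.behavior.vx)
        b.create_dataset("vy", data=session.behavior.vy)
        ug = f.create_group("units")
        for k, u in enumerate(session.units):
            g = ug.create_group(str(k))
            g.create_dataset("spike_times", data=u.spike_times)
            g.attrs["area"] = u.area
            g.attrs["unit_class"] = u.unit_class
            if u.mean_waveform is not None:
                g.create_dataset("waveform", data=u.mean_waveform)
            if u.meta:
                g.attrs["meta_json"] = json.dumps(u.meta, default=float)
        m = f.create_group("meta")
        m.attrs["task"] = session.task
        if session.seed is not None:
            m.attrs["seed"] = int(session.seed)
        if session.meta:
            m.attrs["meta_json"] = json.dumps(session.meta, default=float)


def load_session(path: str | Path) -> Session:
    with h5py.File(path, "r") as f:
        b = f["behavior"]
        behavior = BehaviorTrace(
            vx=b["vx"][...],
            vy=b["vy"][...],
            dt=float(b.attrs["dt"]),
            t0=float(b.attrs.get("t0", 0.0)),
            tracking_noise_sd=float(b.attrs.get("tracking_noise_sd", 0.79)),
        )
        units = []
        for k in sorted(f["units"], key=int):
            g = f["units"][k]
            units.append(
                SortedUnit(
                    spike_times=g["spike_times"][...],
                    area=str(g.attrs.get("area", "M1")),
                    unit_class=str(g.attrs.get("unit_class", "MU")),
                    mean_waveform=g["waveform"][...] if "waveform" in g else None,
                    meta=json.loads(g.attrs["meta_json"]) if "meta_json" in g.attrs else {},
                )
            )
        m = f["meta"]
        return Session(
            behavior=behavior,
            units=units,
            task=str(m.attrs.get("task", "locomotor")),
            seed=int(m.attrs["seed"]) if "seed" in m.attrs else None,
            meta=json.loads(m.attrs["meta_json"]) if "meta_json" in m.attrs else {},
        )


def save_behavior_csv(path: str | Path, behavior: BehaviorTrace) -> None:
    pd.DataFrame(
        {"time": behavior.times, "vx": behavior.vx, "vy": behavior.vy}
    ).to_csv(path, index=False)


def load_behavior_csv(path: str | Path, tracking_noise_sd: float = 0.79) -> BehaviorTrace:
    df = pd.read_csv(path)
    t = df["time"].to_numpy()
    dt = float(np.median(np.diff(t))) if t.size > 1 else 0.01
    return BehaviorTrace(
        vx=df["vx"].to_numpy(),
        vy=df["vy"].to_numpy(),
        dt=dt,
        t0=float(t[0]) if t.size else 0.0,
        tracking_noise_sd=tracking_noise_sd,
    )


def save_raw_trace(path: str | Path, raw: RawTrace) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("voltage", data=raw.voltage)
        f.attrs["fs"] = raw.fs
        if raw.ground_truth:
            ids = np.array([g[0] for g in raw.ground_truth], dtype=np.int64)
            times = np.array([g[1] for g in raw.ground_truth], dtype=float)
            f.create_dataset("gt_template_id", data=ids)
            f.create_dataset("gt_peak_time", data=times)


def load_raw_trace(path: str | Path) -> RawTrace:
    with h5py.File(path, "r") as f:
        gt = []
        if "gt_template_id" in f:
            gt = list(zip(f["gt_template_id"][...].tolist(), f["gt_peak_time"][...].tolist()))
        return RawTrace(voltage=f["voltage"][...], fs=float(f.attrs["fs"]), ground_truth=gt)
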