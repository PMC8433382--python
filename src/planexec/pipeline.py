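"""Pipeline orchestration: simulate → modulate → population → bands →
decode → statespace, with one seed, per-stage outputs and a JSON manifest.

Each stage is a plain function over the library; ``run_pipeline`` wires
them in dependency order, writes HDF5/CSV outputs into a run directory and
records seeds, parameters, wall times and file checksums in
``manifest.json``.  Reruns with the same seed are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .core import InvalidConfigError, Session
from .encode import two_point_decode_sweep, fit_encoding
from .filtering import band_velocity_correlation
from .modulation import (bootstrap_duration, compute_awd, instantaneous_rate,
                         modulation_metrics, planning_sensory_index)
from .population import (decay_timecourse, detect_trials, preprocess_population,
                         trial_correlation_matrix)
from .statespace import lag_tuning_projection, state_vs_frequency
from .synth import BehaviorConfig, UnitSpec, generate_behavior, generate_session

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "modulate", "population", "bands", "decode", "statespace")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``stages`` must respect the dependency order (everything depends on
    ``simulate`` unless ``session_path`` points at an existing session).
    ``params`` holds per-stage keyword overrides, e.g.
    ``{"simulate": {"duration": 300, "n_units": 8}}``.
    """

    out_dir: str | Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    session_path: str | Path | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise InvalidConfigError(f"unknown stages: {sorted(unknown)}")
        order = [STAGES.index(s) for s in self.stages]
        if order != sorted(order):
            raise InvalidConfigError("stages must follow the dependency order")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _default_unit_specs(n_units: int, rng: np.random.Generator) -> list[UnitSpec]:
    """A mixed population: planning, execution and sensory units.

    Half the units are tuned to unsigned speed, half to a signed velocity
    axis (directional tuning), mirroring the mixture found in sensorimotor
    cortex; lags span −1…1 s and modulation widths 0.05…0.4 s.
    """
    lags = rng.uniform(-1.0, 1.0, n_units)
    sigmas = rng.uniform(0.05, 0.4, n_units)
    areas = rng.choice(["S1", "M1", "M2"], n_units)
    drives = [("speed", "vx", "vy")[i % 3 if i % 2 else 0] for i in range(n_units)]
    signs = rng.choice([-1.0, 1.0], n_units)
    return [
        UnitSpec(lag=float(l), modulation_sigma=float(s),
                 gain=4.0 if d == "speed" else float(sg) * 2.5,
                 baseline_rate=3.0 if d == "speed" else 8.0,
                 area=str(a), drive=d)
        for l, s, a, d, sg in zip(lags, sigmas, areas, drives, signs)
    ]


def canonical_session(seed: int = 1, duration: float = 600.0,
                      n_units: int = 12) -> Session:
    """The default synthetic session: locomotor-style behavior plus a mixed
    population of planning / execution / sensory units with random lags."""
    behavior = generate_behavior(BehaviorConfig(duration=duration), seed=seed)
    rng = np.random.default_rng(seed + 1)
    return generate_session(behavior, _default_unit_specs(n_units, rng),
                            seed=seed + 2)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and return the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {},
                      "params": config.params}
    session: Session | None = None
    rates = None
    session_file = out / "session.h5"

    def _finish(stage: str, t0: float, files: list[Path]) -> None:
        manifest["stages"][stage] = {"wall_time_s": round(time.time() - t0, 3)}
        for f in files:
            manifest["outputs"][f.name] = _checksum(f)

    def _need_session(stage: str) -> Session:
        nonlocal session
        if session is None:
            src = config.session_path or session_file
            if not Path(src).exists():
                raise InvalidConfigError(
                    f"stage '{stage}' needs a session; run 'simulate' first "
                    f"or set session_path"
                )
            session = pio.load_session(src)
        return session

    def _need_rates(stage: str):
        nonlocal rates
        if rates is None:
            s = _need_session(stage)
            rates = np.stack([
                instantaneous_rate(u, s.duration) for u in s.units
            ])
        return rates

    for stage in config.stages:
        t0 = time.time()
        p = dict(config.params.get(stage, {}))
        if stage == "simulate":
            n_units = int(p.pop("n_units", 12))
            behavior = generate_behavior(
                BehaviorConfig(**p), seed=config.seed,
            )
            rng = np.random.default_rng(config.seed + 1)
            session = generate_session(
                behavior, _default_unit_specs(n_units, rng), seed=config.seed + 2,
            )
            pio.save_session(session_file, session)
            _finish(stage, t0, [session_file])
        elif stage == "modulate":
            s = _need_session(stage)
            acts = _need_rates(stage)
            n_boot = int(p.pop("n_reps", 0))
            rows = []
            for k, u in enumerate(s.units):
                awd = compute_awd(acts[k], s.behavior)
                prof = modulation_metrics(awd)
                psi = planning_sensory_index(prof)
                row = dict(unit=k, area=u.area, duration_s=prof.duration,
                           lag_s=prof.lag, modulated=prof.modulated,
                           psi_percent=psi, peak=prof.peak_value)
                if n_boot:
                    sd, _ = bootstrap_duration(acts[k], s.behavior,
                                               n_reps=n_boot,
                                               seed=config.seed + 10 + k)
                    row["duration_sd_s"] = sd
                rows.append(row)
            f = out / "modulation.csv"
            pd.DataFrame(rows).to_csv(f, index=False)
            _finish(stage, t0, [f])
        elif stage == "population":
            s = _need_session(stage)
            pop = preprocess_population(s)
            trials = detect_trials(s.behavior)
            files = []
            if trials.n_trials > 0:
                matrix = trial_correlation_matrix(pop, trials)
                tc = decay_timecourse(matrix, **p)
                f = out / "population_tau.csv"
                tc.to_csv(f, index=False)
                files.append(f)
                summary = pd.DataFrame([{
                    "n_trials": trials.n_trials,
                    "tau_premove_s": tc.attrs["tau_premove"],
                    "tau_move_s": tc.attrs["tau_move"],
                    "tau_median_s": tc.attrs["tau_median"],
                }])
            else:
                summary = pd.DataFrame([{"n_trials": 0}])
            f = out / "population_summary.csv"
            summary.to_csv(f, index=False)
            files.append(f)
            _finish(stage, t0, files)
        elif stage == "bands":
            s = _need_session(stage)
            acts = _need_rates(stage)
            df = band_velocity_correlation(acts, s.behavior, **p)
            f = out / "band_velocity.csv"
            df.to_csv(f, index=False)
            _finish(stage, t0, [f])
        elif stage == "decode":
            s = _need_session(stage)
            acts = _need_rates(stage)
            enc = fit_encoding(s, activities=acts)
            df = two_point_decode_sweep(enc.denoised, s.behavior, **p)
            f = out / "decode_sweep.csv"
            df.to_csv(f, index=False)
            _finish(stage, t0, [f])
        elif stage == "statespace":
            s = _need_session(stage)
            acts = _need_rates(stage)
            res = lag_tuning_projection(s, activities=acts)
            agg = state_vs_frequency(res)
            f = out / "statespace.csv"
            pd.DataFrame([{
                "execution_lag_s": res.execution_lag,
                "state_tuning_high": agg["state_tuning_high"],
                "state_tuning_low": agg["state_tuning_low"],
                "n_high": agg["n_high"],
                "n_low": agg["n_low"],
            }]).to_csv(f, index=False)
            _finish(stage, t0, [f])

    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest
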