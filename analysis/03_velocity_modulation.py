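#!/usr/bin/env python
"""Per-unit velocity-modulation metrics on the canonical session.

For every unit: activity-weighted distribution over lags −4…4 s, peak
modulation, duration (80%-of-peak width), lag (midpoint of that region),
modulated call, and the planning-vs-sensory index.  Compares recovered lags
with the generator's ground truth and checks whether duration grows with
|lag| (the temporal-hierarchy trend).  Writes results/modulation.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from planexec.io import load_session
from planexec.modulation import (compute_awd, instantaneous_rate,
                                 modulation_metrics, planning_sensory_index)
from planexec.pipeline import canonical_session
from planexec.stats import CorrectionPolicy, corrected_pearson


def main() -> None:
    path = ROOT / "scratch" / "session.h5"
    session = load_session(path) if path.exists() else canonical_session(seed=1)

    rows = []
    for k, unit in enumerate(session.units):
        act = instantaneous_rate(unit, session.duration)
        prof = modulation_metrics(compute_awd(act, session.behavior))
        rows.append(dict(
            unit=k, area=unit.area,
            true_lag_s=unit.meta.get("true_lag", np.nan),
            lag_s=prof.lag, duration_s=prof.duration,
            peak=prof.peak_value, modulated=prof.modulated,
            psi_percent=planning_sensory_index(prof),
        ))
    df = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    df.round(4).to_csv(ROOT / "results" / "modulation.csv", index=False)

    mod = df[df.modulated]
    err = (mod.lag_s - mod.true_lag_s).abs()
    # a 12-unit toy session cannot absorb the every-7th-unit dependence
    # correction (effective n would be 1); it matters at real unit counts
    trend = corrected_pearson(mod.lag_s.abs().to_numpy(),
                              mod.duration_s.to_numpy(),
                              policy=CorrectionPolicy(1))
    print(f"{len(mod)}/{len(df)} units modulated; "
          f"median |lag error| {err.median()*1000:.0f} ms")
    print(f"duration vs |lag| Pearson r = {trend.statistic:.2f} "
          f"(p = {trend.pvalue:.3f}; uncorrected, n = {len(mod)} units)")
    print("wrote results/modulation.csv")


if __name__ == "__main__":
    main()
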