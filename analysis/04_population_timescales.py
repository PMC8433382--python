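#!/usr/bin/env python
"""Population-correlation time constants across the trial.

Normalizes the population (z-score, column unit-norm, global-mode removal),
detects quiescence→movement trials from the smoothed speed ratio, averages
the 1601 × 1601 within-trial correlation matrices and fits exponential
decays A·exp(−Δ/τ) along the trial.  Writes results/population_tau.csv.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from planexec.io import load_session
from planexec.pipeline import canonical_session
from planexec.population import (decay_timecourse, detect_trials,
                                 preprocess_population,
                                 trial_correlation_matrix)


def main() -> None:
    path = ROOT / "scratch" / "session.h5"
    session = load_session(path) if path.exists() else canonical_session(seed=1)

    pop = preprocess_population(session)
    trials = detect_trials(session.behavior)
    print(f"{trials.n_trials} trials detected "
          f"({pop.n_units} units in the population matrix)")
    if trials.n_trials == 0:
        print("no trials — nothing to fit")
        return
    matrix = trial_correlation_matrix(pop, trials)
    tc = decay_timecourse(matrix, step=0.5)
    (ROOT / "results").mkdir(exist_ok=True)
    tc.round(4).to_csv(ROOT / "results" / "population_tau.csv", index=False)

    print(f"τ at premovement (−1 s): {tc.attrs['tau_premove']*1000:.0f} ms; "
          f"τ at movement (+1 s): {tc.attrs['tau_move']*1000:.0f} ms; "
          f"median τ: {tc.attrs['tau_median']*1000:.0f} ms")
    print("note: the canonical generator has no slow latent state, so τ here "
          "mainly reflects the 50 ms rate smoothing; τ recovery itself is "
          "validated against AR(1) populations with known τ in the test suite")
    print("wrote results/population_tau.csv")


if __name__ == "__main__":
    main()
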