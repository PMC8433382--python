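#!/usr/bin/env python
"""Validate the spike sorter on a synthetic 30 kHz trace with known units.

Embeds three distinct waveform templates (SNR 8) in white noise, runs
threshold extraction and seed-and-neighborhood clustering, and scores the
assignment against the embedded ground truth.  Writes
results/sorting_accuracy.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from planexec.sorting import extract_snippets, mu_rate, sort_snippets
from planexec.synth import generate_raw_trace, make_templates

SEED = 1
DURATION = 300.0


def main() -> None:
    templates = make_templates(3, peak_amplitude=-80.0, seed=0)
    raw = generate_raw_trace(templates, rates=2.0, noise_sd=10.0,
                             duration=DURATION, seed=SEED)
    snippets = extract_snippets(raw)
    result = sort_snippets(snippets, seed=SEED + 1)

    gt_t = np.array([g[1] for g in raw.ground_truth])
    gt_id = np.array([g[0] for g in raw.ground_truth])
    rows, correct, total = [], 0, 0
    for k, unit in enumerate(result.units):
        ids = []
        for t in unit.spike_times:
            j = int(np.argmin(np.abs(gt_t - t)))
            ids.append(gt_id[j] if abs(gt_t[j] - t) < 0.002 else -1)
        ids = np.asarray(ids)
        vals, counts = np.unique(ids[ids >= 0], return_counts=True)
        majority = int(vals[np.argmax(counts)]) if vals.size else -1
        hit = counts.max() if vals.size else 0
        correct += hit
        total += ids.size
        rows.append(dict(unit=k, n_spikes=unit.n_spikes, unit_class=unit.unit_class,
                         majority_template=majority, purity=hit / ids.size))
    accuracy = correct / total if total else float("nan")
    df = pd.DataFrame(rows)
    df.attrs["accuracy"] = accuracy
    (ROOT / "results").mkdir(exist_ok=True)
    out = ROOT / "results" / "sorting_accuracy.csv"
    df.round(3).to_csv(out, index=False)

    # μ-rate on the embedded ground-truth trains: sorted units on one channel
    # are censored near lag 0 (colliding waveforms resolve to one trough),
    # which would drag the minimum to zero regardless of decorrelation
    from planexec.core import SortedUnit

    t0 = SortedUnit(gt_t[gt_id == 0])
    t1 = SortedUnit(gt_t[gt_id == 1])
    mu = mu_rate(t0, t1, DURATION)
    print(f"{snippets.n} snippets → {len(result.units)} sorted units; "
          f"assignment accuracy {accuracy:.1%} (3 templates, SNR 8)")
    print(f"μ-rate between the embedded trains: {mu:.0f}% of the average rate "
          f"(≈100% = decorrelated; the minimum of ~2000 Poisson-count lag "
          f"bins sits below 100% by the sampling floor at this spike count)")
    print(f"wrote {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
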