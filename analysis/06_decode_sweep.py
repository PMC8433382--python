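#!/usr/bin/env python
"""Frequency-swept two-point decoding of paw velocity.

De-noises each unit by encoding it from the lagged 2-D velocity (T = 400
taps), then decodes velocity per band with only two weights per unit (lags
−1/f and 0) — the restriction that prevents trivial inversion of the
encoder.  Repeats with white noise matched to the raw residual added back,
reproducing the noise-driven shift of the optimal band.  Also extracts the
unit-specific decoding kernels and their rise-latency statistics.  Writes
results/decode_sweep.csv and results/unit_kernels.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from planexec.encode import (fit_encoding, two_point_decode_sweep,
                             unit_kernel_analysis)
from planexec.io import load_session
from planexec.modulation import instantaneous_rate
from planexec.pipeline import canonical_session


def main() -> None:
    path = ROOT / "scratch" / "session.h5"
    session = load_session(path) if path.exists() else canonical_session(seed=1)
    acts = np.stack([instantaneous_rate(u, session.duration)
                     for u in session.units])

    enc = fit_encoding(session, activities=acts)
    clean = two_point_decode_sweep(enc.denoised, session.behavior)
    noisy = two_point_decode_sweep(enc.noisy(seed=7), session.behavior)
    merged = clean.rename(columns={"performance": "performance_denoised"})
    merged["performance_noisy"] = noisy["performance"]
    (ROOT / "results").mkdir(exist_ok=True)
    merged.round(4).to_csv(ROOT / "results" / "decode_sweep.csv", index=False)
    print(f"mean encoding r² = {enc.r2.mean():.3f} across {len(enc.r2)} units")
    print(f"de-noised decoding peaks at {clean.attrs['argmax_freq']:.2f} Hz; "
          f"with residual-matched noise: {noisy.attrs['argmax_freq']:.2f} Hz")

    kern = unit_kernel_analysis(session, activities=acts, seed=11)
    fit = kern.fit_r[np.arange(len(kern.dominant_axis)), kern.dominant_axis]
    pd.DataFrame({
        "unit": np.arange(kern.kernels.shape[0]),
        "dominant_axis": np.where(kern.dominant_axis == 0, "x", "y"),
        "fit_r": fit,
        "derivative_peak_s": kern.derivative_peak_time,
        "rise_latency_s": kern.rise_latency,
    }).round(4).to_csv(ROOT / "results" / "unit_kernels.csv", index=False)
    # latency stats over well-fit kernels only (weak kernels give noise
    # latencies), mirroring the SNR restriction used for kernel displays
    good = fit > 0.1
    lat = kern.rise_latency[good]
    print(f"kernel rise-latency SD across {good.sum()} well-fit units: "
          f"{np.nanstd(lat)*1000:.0f} ms (true lags span −1…1 s)")
    print("wrote results/decode_sweep.csv and results/unit_kernels.csv")


if __name__ == "__main__":
    main()
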