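# Methods

This note documents the models and numerical choices behind `planexec`:
what the synthetic generator does and does not emulate, the exact
definitions of each analysis stage, and the places where the design was
genuinely open and a choice had to be made.

## Synthetic sessions

### Behavior

Real paw-velocity traces from freely moving rats are not publicly
deposited, so the generator states an explicit world with the statistical
features the analyses rely on:

- **Sub-movement pulses.** Speed is a train of Gaussian pulses
  (σ = period/6) on a jittered grid at `submovement_freq` (default
  4.7 Hz, relative interval SD 0.2). The quasi-periodic train puts the
  spectral peak of the *speed* trace at the pulse rate, matching the
  observed ~210 ms peak-to-peak velocity time.
- **Return strokes.** Each pulse points along a slowly rotating movement
  axis and reverses the previous pulse with probability 0.9. This encodes
  a physical constraint — the paw workspace is bounded, so velocity cannot
  have DC power — and concentrates the *signed* velocity components near
  half the pulse rate (≈ 2.3 Hz). Without it the components inherit the
  slow bout envelope and every low-frequency analysis is dominated by
  drift that real limb velocity does not have.
- **Quiescence/movement alternation.** A two-state semi-Markov gate
  (gamma-distributed dwells, means 4 s active / 2 s quiet, shape 2)
  scales pulse amplitudes, giving the low-speed → high-speed transitions
  the trial detector needs. The gate is a stand-in: nothing is claimed
  about rodent bout statistics beyond "bouts last a few seconds".
- **Tracking noise.** White Gaussian noise of SD 0.79 cm/s per axis — the
  published estimate of the camera-tracking noise — is added to both
  velocity components.

Not emulated: position bounds (velocity is generated directly), multi-limb
coordination, posture, reward-dependent structure of the joystick task.
A green test on this world therefore establishes that an analysis recovers
the structure it targets *when that structure is present as stated*; it
says nothing about robustness to, e.g., postural slow drift.

### Units

A unit's rate is `baseline + gain · link(drive(t − lag))`, floored at 0 and
capped at 500 Hz, where the drive is speed (unsigned tuning), or vx/vy
(signed directional tuning), smoothed with a Gaussian of SD
`modulation_sigma`. Negative `lag` means the activity *leads* the
movement. The link is linear or exponential (`expm1(x/4 cm s⁻¹)`), the
latter exercising the nonlinear tuning the binned AWD is designed to
capture. Spikes are an inhomogeneous Poisson process (per-10 ms Poisson
counts, uniform jitter within the bin).

The default mixed population (12 units) spans lags −1…1 s, widths
0.05…0.4 s, and half-unsigned/half-signed drives. Gains (2.5–4 Hz per
cm/s on baselines of 3–8 Hz) put peak rates in the 10–40 Hz range typical
of sensorimotor units.

### Raw voltage

For the sorter, 76-sample biphasic templates (trough at sample 16,
1-based) are superimposed at Poisson times (2 ms refractory per template)
on white noise at 30 kHz. The bundled template designs differ in trough
width, amplitude, and rebound/pre-bump geometry so that they are genuinely
separable at SNR 8 — pairwise distances exceed twice the noise radius
√(2·76)·σ, which is the stability condition of the center-based
neighborhood rule.

## Spike sorting

The 300 Hz high-pass before thresholding is **causal** (forward
Butterworth): a zero-phase filter would smear each spike's energy backward
into the sample 0.5 ms before its trough, and that sample is exactly where
the cluster-size noise level is estimated (the refractory period guarantees
the unit itself contributes nothing there — but only for a causal filter).

Cluster radius: the SD of the pre-trough sample over the current snippet
set, scaled by √(2·dim). Two spikes of one neuron differ by two
independent noise draws, so √(2·dim)·σ is their expected Euclidean
distance; a √dim·σ ball (distance to the cluster *mean*) leaves the
seeding phase — which counts neighbors of a snippet, not of a mean — with
empty neighborhoods. A per-dimension box variant is available
(`per_dimension=True`).

SU/MU rule: the spike count inside the < 2 ms ISI window is converted to
an ISI-histogram density (count / (n_isi · 2 ms)) and compared with the
unit's average rate. For a Poisson train the two are equal; a refractory
single unit falls below; a mixture reaches or exceeds. (A per-session
violation *rate* would never exceed the average rate below 500 Hz and
would classify everything as SU.)

## Velocity modulation

AWD sign convention: the value at lag *l* pairs activity(t + l) with
behavior(t), so movement-leading activity peaks at negative lags. Cells
with no occupancy are NaN and excluded from all means; the per-lag mean
over bins is unweighted (occupancy weighting would let the quiescent bin
dominate). The modulated criterion normalizes by mean and SD over the
union of the −4…−3 s and 3…4 s stretches and thresholds the peak at 10.

The segment bootstrap accumulates per-(lag, bin) sums and counts per
contiguous segment and pools resampled segments as a count-weighted mean —
the natural pooled estimate when segments contribute unequal occupancy.

Estimator precision at desk scale: the modulation curve's sampling noise
is low-frequency (activity smoothing correlates neighboring lags), so the
80 %-crossing positions jitter by ~25 ms for broad tuning regardless of
gain. Sharp tuning (σ = 0.05 s) is localized to ±30 ms; the 80 %-width of
broad tuning carries ~20–40 % per-unit scatter at 600 s and is validated
in aggregate. Both regimes are exercised in the acceptance tests.

## Population correlations

Pipeline: per-unit z-score over the session → per-column demean and
unit-norm → projection out of the global mode p. With a single task, p is
the normalized mean population vector over the lowest-decile speed epochs
(the cross-task freezing correlation that defines p in paired recordings
is unavailable); this is an interpretation, flagged as such. Column norms
after p-removal are ≤ 1 and columns are exactly orthogonal to p.

The decay fit A·e^(−Δ/τ) uses least squares with τ ∈ [0.01, 20] s,
A ∈ [0, 1.5], τ initialized at the distance where correlation first falls
below A₀/e. The τ timecourse restricts each fit to Δ ≤ 2 s around its
reference bin so the estimate stays local when τ varies across the trial;
1/τ is the frequency at which a first-order low-pass attenuates amplitude
to 1/√(1+4π²) ≈ 16 %.

Trial detection divides the 2 s-FWHM-smoothed speed by its value 2 s
earlier; ratio maxima above 2 are trial centers (local maxima taken on the
ratio trace, one of two possible readings). The behavioral-frequency
estimator (smallest Gaussian low-pass cutoff whose reconstruction error is
within the tracking noise) is likewise an interpretation of a verbal
description.

## Filtering

All bands are subtractive-Gaussian with reflection padding (4σ). The band
table pairs the i-th high-pass σ with the i-th low-pass σ
(ratio ≈ 4) and labels bands by the low-pass cutoff: 11, 4.5, 2.2, 1.1,
0.45, 0.22, 0.11 Hz. The 11 Hz band's σ_lp is 1.4 samples on the 10 ms
grid — below 2 samples the kernel is coarse but still well defined;
only σ < 1 sample is rejected. Note the printed "2.3 Hz" frequency of the
decoding analyses is this table's 2.2 Hz band (1/(2π·0.071 s)).

Cross-frequency coupling: slow-band phase via Hilbert transform, fast-band
amplitude as the rectified band-passed signal smoothed at 1.5 Hz, averaged
in 16 phase bins.

## Encoding / decoding

Encoding (de-noising) is plain OLS of each unit's rate on the 800-column
lagged velocity design (T = 400 per axis, lags −2.00…+1.99 s); a ridge is
added only on rank deficiency, and the fit is flagged. The noise-matched
variant adds white Gaussian noise with the raw residual SD.

The two-point decoder fits 2·U weights per axis (activity at lags −1/f,
rounded to the grid, and 0) by OLS; performance is the Pearson r between
decoded and measured velocity, averaged over axes (the metric is a
choice — the source describes "decoding performance" without naming one).
Axes are decoded independently. Fits are in-sample by default; a blocked
2-fold split is available (`split=True`).

Unit-specific decoding kernels regress each *single* unit's lagged
activity onto each velocity axis. Four hundred lagged copies of a
50 ms-smoothed rate are strongly collinear, so these fits carry a ridge of
0.1 × the mean eigenvalue of XᵀX and use only rows with full ±2 s support;
without both, the solution is a noise-amplifying oscillation (the in-sample
r is unchanged by the ridge — the suppressed directions carry no signal).
The dominant axis per unit is the one with the higher in-sample decode r,
not the larger kernel norm (a pure-noise kernel can out-norm a true one).
Kernels are analysed with a generalized Morse CWT (symmetry γ = 1.5,
time–bandwidth βγ = 2, 12 voices/octave over 0.25–30 Hz, FFT-domain
analytic wavelet with unit peak), the time of the largest rectified
derivative, and the 50 %-of-extremum rise latency (linear interpolation on
the rising flank). Kernel-weight variability comes from resampling 10 s
segments' normal equations.

## State space

Velocity-lag tuning(n, l) is the plain time average of v_AP(t)·r_n(t+l)
over all bins (r_n z-scored), lags −1…1 s. PCA is computed on the
lag-mean-centered matrix. The potent axis defaults to the normalized
trajectory point at −40 ms; passing `execution_lag=None` re-derives it per
session as the lag in [−100, 0] ms whose trajectory point correlates least
with the mean trajectory over the planning window (−1000…−200 ms).
Frequency dominance filters the reduced trajectory itself along the lag
axis at the 1.1 Hz split (the signal being filtered was not stated in the
source description; filtering the trajectory matches how its time course
is displayed and is flagged as an interpretation).

## Statistics

The dependence factor (default 7) shrinks degrees of freedom to n // 7
(floored) for t-tests, ANOVA and Pearson tests — the statistic itself is
classical, so factor 1 reproduces the textbook tests exactly — and scales
block-bootstrap SDs by √7. With factor > 1 corrected p-values are never
smaller than uncorrected ones on the same data.

## Known limitations

- The generator contains no slow latent population state, so population τ
  on canonical sessions reflects the 50 ms rate smoothing; τ recovery is
  validated against AR(1) populations with known τ instead.
- Sorted units on a single channel are mutually censored within one
  snippet window (colliding waveforms keep only the deeper trough), which
  pulls pairwise μ-rates toward 0 at lag 0; μ-rate behavior is therefore
  validated on generated spike trains.
- All de-noising/decoding fits are in-sample, as in the source procedure;
  the blocked split exists but is not the default.
- Subthreshold-reconstruction and auto-encoder de-noising tools are out of
  scope; spike trains enter the frequency analyses as Gaussian-smoothed
  (σ = 50 ms) instantaneous rates, which preserves the band structure the
  analyses compare but attenuates content well above ~6 Hz.
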