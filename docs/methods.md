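# Methods

This note documents the models, defaults and design decisions behind
`mobiqc`: what each stage assumes, which knobs matter, what the synthetic
generator does and does not emulate, and where genuinely open choices were
resolved.

## Device profiles

Five built-in profiles describe the headsets the package models: two
high-resolution dry systems at 256 Hz with 0.29 µV/step 24-bit ADCs and a
±2,400 mV input range (4- and 32-channel), an 8-channel dry system at
500 Hz / 0.05 µV, a 16-channel dry system at 512 Hz / 0.05 µV (±410 mV),
and a 32-channel gel reference system at 1,000 Hz / 0.1 µV with a 16-bit
ADC and a ±3.28 mV input range.  Resolution drives both the lower QC
threshold (10×resolution) and the simulator's quantization; the input
range sets the clipping rail and the poor-contact saturation value.

Montages are editable defaults.  Only the shared-electrode structure is
load-bearing: Fp1/Fp2 are shared by four systems, F3/F4/C3/C4/P3/P4 by
four, and O1 by three, so the commonality rule (an electrode is analyzed
across the headsets that share it, provided at least three do) yields
exactly nine analysis electrodes over the five montages.  The remaining
sites are conventional extended 10–20 choices and are not asserted as any
particular vendor's layout.  With fewer than three montages in play the
sharing requirement drops to the montage count, so two identical montages
are fully analyzable.

## Synthetic sessions

The generator renders a session as a sequence of conditions — one 60 s
eyes-open resting baseline and one or more free-viewing intervals — and is
the package's only data source, since recordings of this kind are not
publicly available.  Per channel it sums:

* **1/f^a colored Gaussian background**, default a = 1 and 10 µV RMS,
  shaped in the frequency domain.  10 µV RMS puts typical peak-to-peak
  excursions in the tens of microvolts, the usual scalp-EEG range, and
  leaves a clean session below the 300 µV threshold with very high
  probability.
* **Band oscillations**: an amplitude-modulated 10 Hz sinusoid on
  posterior channels and a 20 Hz sinusoid on frontal channels (0.2 Hz
  sinusoidal envelope, depth 0.5, random phases), scaled to a per-condition
  RMS target.  Defaults are 6 µV alpha / 1.5 µV beta at baseline and
  2 µV alpha / 4 µV beta during viewing: resting eyes-open posterior alpha
  several-fold above its level during engaged viewing (classic alpha
  blocking, a ~9× power ratio), and frontal beta rising with engagement.
* **Eye blinks** on frontopolar channels: biphasic difference-of-Gaussians
  pulses of 300 ms width and ~100 µV peak (±20% jitter), Poisson arrivals
  at 15/min with a refractory gap of one pulse width so blinks never
  superpose.
* **Artifacts** from the five-class taxonomy, injected from an explicit
  plan (spans or Poisson rates, non-overlap enforced by shifting later
  arrivals).  Shapes follow the physical failure modes: pops are isolated
  bursts with a guaranteed 400 µV peak on one channel; poor contact
  alternates attenuated signal with saturation at the device rail;
  digitization error replaces the signal with a clipped ±3-step random
  walk on the ADC grid; wireless loss freezes all channels at the last
  transmitted value; flat lines hold affected channels constant.  Flat
  lines on *all* channels are refused as a failed recording rather than an
  artifact.  Ground-truth spans are snapped to the sample grid so labels
  and modified samples agree exactly.
* **Quantization**: rounding to the nearest multiple of the device
  resolution (half away from zero) and clipping at the input range.

What the generator does **not** emulate: volume conduction and realistic
cross-channel covariance (channels are independent apart from shared blink
timing), gait/motion artifacts, line noise, non-stationary background
spectra, electrode drift, and inter-subject variability beyond the seed.
Passing tests therefore demonstrate correct mechanics of thresholding,
spectral estimation and clustering — not field performance on real scalp
data.

A second, spectral-domain generator (`three_class_spectra`) draws
normalized PSDs directly from three shape families — plain 1/f, 1/f plus a
10 Hz Gaussian peak, concave-down — with per-bin multiplicative
Gamma(7, 1/7) noise, the sampling distribution of a 7-taper multitaper
estimate.  It provides ground truth for cluster-count recovery without a
full session simulation.

## Preprocessing

The band-pass is a 4th-order Butterworth design applied forward–backward
(`sosfiltfilt`), read as "4th-order zero-phase": the effective magnitude
response is the squared 4th-order response and the phase is identically
zero.  Stage order is filter → threshold QC → subspace cleaning → common
average reference → windowing.  CAR is computed after channel rejection,
so only retained channels enter the average (the alternative ordering is
not distinguishable from published descriptions of such pipelines; this
one prevents rejected channels from contaminating the reference).

The subspace cleaner is a simplified artifact-subspace-reconstruction
scheme.  Calibration data (by default the baseline condition) define a
covariance `C`; its symmetric square root `M = C^{1/2}` is the mixing
matrix and `W = M^{-1}` the whitener.  Sliding 0.5 s windows with 50%
overlap are analyzed in the whitened space: the window covariance is
eigendecomposed and each component's variance is compared with a per-rank
threshold, mean + 3 SD of the same statistic over calibration windows.
Exceeding components are **shrunk** to the threshold
(gain `sqrt(threshold/variance)`) rather than replaced outright, and the
window is mapped back through `M`.  Shrinkage makes the cleaner a strict
no-op in the limit `cutoff_sd → ∞`, keeps it within sampling fluctuation
of the identity on calibration-distributed data (hard replacement of
marginally-exceeding components would not be), and makes it idempotent up
to tolerance, while still collapsing genuine bursts (a 10× variance burst
retains ~20% of its variance after one pass).  Windows are blended with a
linear cross-fade so seams stay continuous.  Rank-deficient calibration
covariances are floored at 1e−9 of the largest eigenvalue with a logged
warning.

## Quality control

"Amplitude" means the absolute value of the 1–50 Hz filtered signal; the
QC stage can be pointed at raw data via `qc.on_filtered: false`.  Channel
rules use occupancy: reject for *upper* when |x| > 300 µV on more than
20% of samples, for *lower* when |x| ≥ 10×resolution on fewer than 20% of
samples (i.e. the channel sits below threshold at least 80% of the
session); *upper* wins when both hold.  Window rejection is stricter —
any supra-upper sample on a retained channel marks a region, regions are
dilated by 0.5 s each side (clipped at recording edges), and every window
intersecting a dilated region is dropped.  Both occupancy readings that
circulate for the lower rule ("below for ≥20%" vs "below for ≥80%") are
representable; the 80% reading is the default because it is the only one
consistent with the channel-level statistics the pipeline reports.

The five-class classifier mechanizes what would otherwise be visual
inspection: wireless loss is an all-channels-constant run ≥ 0.1 s; flat is
a single-channel constant run ≥ 1 s outside wireless spans; supra-upper
excursions (merged across gaps < 0.2 s) become poor contact when ≥ 3 fall
within 5 s of each other and pops when isolated and < 1 s; digitization
error is flagged per 1 s block when ≥ 95% of successive absolute
differences are within 2 ADC steps, the amplitude stays sub-lower, and the
block is not constant.

## Spectral features

Each 4 s window is estimated with Thomson's multitaper method: 2NW−1 = 7
DPSS tapers at NW = 4, eigenvalue-weighted, one-sided density scaling, FFT
length max(512, window length).  The estimate is linearly interpolated
onto 256 equally spaced bins on [1, 50] Hz ("downsampling" is otherwise
underspecified; linear interpolation on the density is monotone and
grid-stable).  Normalization divides by the summed bin values — after
normalization this is scale-equivalent to an integral convention.
Standardization pools all samples of an electrode across headsets and
conditions, z-scoring each bin; numerically-zero-variance bins are set to
0 with a warning.  Band limits: delta 1–4, alpha 8–12, beta 12–30, gamma
30–50 Hz (delta/gamma are package defaults, gamma capped by the 50 Hz
low-pass); bands are half-open except the top edge of gamma, which
coincides with the grid end.

## Kernel clustering

Kernels: linear; inhomogeneous polynomial `(x·y + 1)^d`, d ∈ {2, 3};
Gaussian `exp(−‖x−y‖²/(2σ²))` over the σ ladder
{4, 12, 14, 20, 22, 24, 26, 28, 36, 44, 52, 60} in standardized-feature
units (the `exp(−d²/σ²)` convention is available via
`KernelSpec(..., convention="sigma2")`).  Screening scores each candidate
by the Shannon entropy (bits) of a 32-bin histogram of its off-diagonal
values over their observed range — the "most well-distributed
similarities" criterion — and keeps the argmax.

Cluster-count selection uses the uncentered kernel eigendecomposition and
the uniform weight vector `w` with entries 1/N, so `wᵀKw` is the mean
kernel value and the terms λᵢ(wᵀuᵢ)² decompose it exactly.  The default
rule takes k at the largest relative gap `(tᵢ − tᵢ₊₁)/tᵢ` of the
descending-sorted terms, capped at `k_max = 10`; a threshold alternative
(count of terms above τ = 0.05 of the maximum) is available.  Degenerate
term sequences (all equal or all zero) return k = 1 with a warning.  On
strongly blocked kernels the rules agree; on weakly structured data the
first (mean) term can dominate and the gap rule returns small k, which is
why the bundled demo pins k = 5 across electrodes — the same
"for consistency" choice the original analysis made — while `k: auto`
remains a config switch.

Kernel K-means runs Lloyd iterations purely on the Gram matrix,
`d(i, c) = K_ii − (2/|c|)Σ_{j∈c}K_ij + (1/|c|²)Σ_{j,l∈c}K_jl`, to
convergence or 300 iterations, from 200 uniformly random initial
assignments (each restart seeded from a spawned substream, so results are
reproducible and ties resolve to the lowest restart index).  Empty
clusters are reseeded with the point farthest from its centroid.  The
objective is the within-cluster variance in feature space,
`trace(K) − Σ_c (1/|c|)Σ_{i,j∈c}K_ij`, and is recomputed from the final
assignment.  An independent exhaustive enumerator (vectorized over all
k^(N−1) anchored labelings, N ≤ 12) provides the global optimum for
verification.

Per-cluster condition shares are tested with an exact two-sided binomial
test of the cluster's baseline count against the pooled baseline share,
significant at p < 0.01 (99% confidence).

## Pipeline and problem sizes

The bundled demo simulates two subjects on each of three headsets
(60 s baseline + 180 s viewing; pops at 0.5/min and wireless dropouts at
0.2/min), yielding ~6,400 spectral samples over the nine shared
electrodes, and clusters each electrode after kernel screening.  These
sizes keep a full run around half a minute on one CPU while leaving every
stage's statistics well-resolved; they are the package's default study
scale, not a constraint of the method.  The acceptance script scales the
same checks: 100 random matrices for the eigen identity, 100 small
instances against exhaustive enumeration, 20 seeds for k-recovery and QC
detection.

## Known limitations

* The subspace cleaner is not the published ASR algorithm: calibration is
  a plain covariance (no geometric-median robustification), thresholds are
  per-rank variance statistics, and flagged subspaces are shrunk rather
  than reconstructed by truncated back-projection.
* The artifact classifier is rule-based and tuned to the generator's
  artifact shapes; real devices produce intermediate morphologies that
  would need per-device calibration of the run-length and gap constants.
* Channel independence in the simulator means CAR and the subspace
  cleaner are exercised on weaker cross-channel structure than real EEG
  provides.
* The eigen-term k rule inherits the ambiguity of "dominant terms": both
  implemented rules are deterministic, but neither reproduces a human
  eyeballing a scree plot in all regimes.
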