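# Methods

This note documents the models, the numerical choices, the tunable
parameters, and the limits of what the synthetic recordings can show. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Signal model and conditioning

Recordings are an `n_acoustic × n` matrix of raw (uncalibrated) acoustic
samples plus a 3 × n accelerometer matrix in g, at a common sampling rate
`fs`. All times are seconds from recording start; intervals are half-open
`[start, end)`.

Three conditioning operators precede everything else, all applied
forward-backward (zero-phase) so that event timing is never skewed by group
delay — verified in the tests by locating the peak of a filtered impulse:

* **Comb notch.** Cascaded second-order IIR notches at `mains_hz·k`,
  k = 1..`n_harmonics` (default: every harmonic below Nyquist), quality
  factor Q = 30. `mains_hz = 0` disables the stage. The original
  acquisition electronics introduced narrowband interference; the filter
  family is fixed here as cascaded biquad notches, the simplest realization
  consistent with that purpose.
* **De-noising.** 4th-order Butterworth low-pass, default corner 20 Hz.
  Movement energy concentrates below ~10 Hz, so a 20 Hz corner preserves the
  whole physiological band (passband ripple < 1 % below half the corner)
  while removing wideband sensor noise. Chosen as the simplest operator
  meeting those spectral facts; the corner is configurable.
* **Envelope.** Moving average over `env_window_s` (default 0.25 s) of |x|
  on the segmentation path, of x itself on the discrimination path.
  0.25 s is short enough to resolve ~1 s startles and long enough to smooth
  sample noise. Edges shrink the window (a constant input maps to itself).
  On the discrimination path the pipeline's default excision uses the
  conditioned signal *without* the moving average: a 0.25 s average is a
  ~4 Hz low-pass and would destroy the 6–9 Hz feature band. The unrectified
  envelope remains available for configurations with narrower windows.

## Segmentation

Noise floor = median of the channel envelope. The median is robust in the
sparse-activity regime (bursts < 10 % duty cycle barely move it, which the
tests check by Monte-Carlo). A channel's ROIs are maximal runs of
`env > snr_threshold · floor` after closing gaps shorter than `gap_close_s`
and discarding runs shorter than `min_duration_s`; each ROI carries
SNR = mean in-ROI envelope / floor. Thresholding is *relative*, so
segmentation is exactly invariant to amplitude rescaling of the recording.

Defaults (all exposed in `SegmentationConfig`): `snr_threshold = 3`,
`min_duration_s = 0.1 s`, `gap_close_s = 0.5 s`. These are this package's
own operating point: threshold 3 puts the false-alarm rate on pure noise
below about one candidate per minute while leaving high-SNR bursts intact.

Maternal exclusion is interval-level, not sample subtraction: each
accelerometer axis is high-passed at 0.5 Hz (removing gravity), the vector
magnitude is enveloped and thresholded at 0.1 g, flagged runs are padded
±0.5 s and merged. A ROI is vetoed when the mask covers ≥ 50 % of it
(`maternal_overlap_frac`, inclusive at the boundary). Channels are
thresholded first and fused afterwards (union across channels with the same
gap closing); the fused candidate records the contributing channels.
All-zero channels are skipped with a warning rather than aborting a scan.

## Matching

The annotation window is `[t − 3.5 s, t + 1.5 s)`, clamped to the recording:
the call-out lags the movement, so most of the window reaches into the past.
Same-type annotations closer than 5 s merge into one movement, anchored at
the first of the cluster; the merge is *rolling* by default (10, 13, 16 s
all merge) with a flag for anchor-at-cluster-start behaviour, and merging is
per movement type, so an interleaved annotation of another type neither
merges nor breaks a chain. This makes the operation idempotent.

An annotation is detected iff its window intersects ≥ 1 candidate. The
annotation is the unit of detection: several candidates in one window count
once, and one candidate may detect several annotations (no assignment
problem is solved). Candidates overlapping probe-repositioning intervals are
excluded before matching by default — such candidates are plausibly the
examiner touching the sensors. Rates for unobserved types are reported as
absent, never 0 %. Pooled-over-annotations rates are the default report;
per-subject means are also available from the per-scan results.

The scrambled control redraws each candidate's start uniformly in
`[0, duration − d]`, preserving the count and duration multiset (nothing
else), merges any resulting overlaps, re-matches, and averages over seeded
replicates. Its mean converges to the probability that a tolerance window
intersects at least one randomly placed interval, which the tests verify
against an independent placement simulation.

## Discrimination

Feature vector (12 components) per selected ROI — the overlapping ROI with
maximal SNR, ties to the lowest channel index, excised from the
non-rectified conditioned channel:

1. duration (s);
2. energy Σx² (signal-units²);
3. Shannon entropy (bits) of the normalized periodogram — tones score low,
   broadband noise high;
4. six wavelet detail-band energies: Daubechies-4 `wavedec` at depth
   `round(log2 fs)` so the coarsest detail band reaches ~0.5 Hz; the six
   coarsest bands then tile ≈ 0.5–32 Hz at fs = 128 Hz, each reported as a
   fraction of total detail energy. Segments shorter than the decomposition
   support are zero-padded at the tail (zeros add no energy, so the
   fractions remain those of the burst); segments shorter than the db4
   filter support are rejected with the minimum length in the message.
   Which six coefficients the original device used is not recoverable, so
   the choice of family (db4) and banding is this package's own and is
   isolated behind the feature function.
5. three band-energy ratios: periodogram energy in 1.1–1.5, 2.2–3 and
   6–9 Hz, each divided by the 0.5–20 Hz total (a full-band denominator is
   a config option).

Classification standardizes features (constant columns dropped with a
warning), projects on the first three principal components for numerical
stability, and runs leave-one-out: the held-out row is predicted by a model
fit on all others, accumulating a 2×2 confusion matrix per class pair
(breathe/startle, general/startle, breathe/general), reported as
row-normalized percentages with row totals. `pca_scope="fold"` (default)
refits scaler and PCA inside every fold, avoiding leakage;
`pca_scope="global"` reuses one transform, matching a one-shot-PCA reading
of the protocol. kNN uses k = 5, Euclidean distance in PCA space; with odd
k and two classes vote ties cannot occur. Class imbalance is left as-is by
default. LDA and QDA are drop-in alternatives. The kNN jackknife is tested
for exact count equality against a brute-force oracle that refits
standardization, PCA (eigendecomposition) and the vote from scratch per row.

Average per-class spectra are periodograms on a common zero-padded grid,
each rescaled to integrate exactly to its ROI's energy (Parseval by
construction) before within-class averaging.

## Synthetic data

The generator embodies the statistical structure the analysis assumes; its
defaults are the study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| scan duration | 1200 s | ~20 minutes per subject |
| channels / fs | 6 acoustic + accel, 128 Hz | ultrasound-compatible sensor count; fs covers the < 32 Hz band of interest |
| event rates | breathe 5.8, general 1.5, startle 0.87 /min | cohort totals 5251/1354/780 over 900 min |
| startle model | 0.5–1.5 s, 3–8 Hz, amplitude 8–12 | "about a second", most vigorous |
| general model | 1–4 s, 1–5 Hz, amplitude 3–6 | longer, moderate |
| breathing model | 1.5–3.5 s trains, period 0.8–1.5 s, 0.5–1.5 Hz, amplitude 0.8–1.5 | rhythmic, low amplitude |
| attenuation | (d₀/(d + d₀))^1.5, d₀ = 0.1 | nearest sensor sees an event strongest |
| maternal events | 0.5 /min, ≥ 0.1 g transient + correlated acoustic wobble | gives the IMU mask something real to veto |
| noise σ | 0.3 | places a nearest-channel startle near envelope SNR ~10 (high-SNR regime) |
| reaction delay | uniform 0.5–3.5 s | annotation lags movement; the 3.5 s window reach recovers it |
| gestational ages | uniform 24+3 – 34+6 weeks | inclusion window |

Amplitudes are arbitrary units; envelope SNR is the controlled quantity
because the real sensors are uncalibrated. Bursts are Gabor atoms (Gaussian
window × sinusoid), which concentrates all class energy below 10 Hz by
construction. Event draws are homogeneous Poisson; a per-class capacity
check rejects configurations whose expected single-class busy time exceeds
the scan. Cohorts fan one master seed into per-subject substreams; the
breathing rate scales log-linearly with gestational age (default
0.15/week) under lognormal between-subject heterogeneity (σ = 0.4), with
each class's rate clipped to an expected duty cycle ≤ 80 %. Cohort counts
are tallies of the same event draw that scan synthesis uses, so the data
record is consistent with its own recordings.

What the simulator does **not** emulate: fetal/maternal cardiac signals,
digestive sounds, tissue acoustics and sensor coupling variability,
non-Poisson behavioural state cycling, observer misses or mislabels, and
clock drift. Passing tests on synthetic scans therefore demonstrate the
*internal* correctness and calibration of the pipeline (segmentation
recovers what the generator planted; nulls sit where placement geometry says
they should), not field performance on real abdomens.

## Numerical choices and degenerate inputs

* Zero-phase filtering throughout; envelope edge handling by window
  shrinking.
* SNR tie in best-ROI selection → lowest channel index; kNN distance ties →
  stable neighbour order.
* Degenerate all-zero envelopes yield a warning and no ROIs; empty masks and
  empty candidate sets are valid; zero observed movements make rates and the
  candidate-to-seen ratio *absent*, not zero.
* Recording/annotation CSVs round-trip within 1e-9 relative (values printed
  at 12 significant digits).
* Gestational age "W+D" is stored as W + D/7 decimal weeks; days outside
  0–6 are rejected.
* Spearman correlations use average ranks on ties with seeded permutation
  p-values; all-constant factors are reported absent.

## Problem sizes in the checks

The validation suite sizes are the package's own choices: the end-to-end
recovery check uses 20 simulated 20-minute scans with 10 scramble replicates
each; null calibration uses 1000 replicates against a 1000-replicate
placement oracle; discrimination recovery uses 50 seeds × 30 bursts per
class; oracle-equality checks use instances of ≤ 30 rows where exact count
agreement is required. `scripts/acceptance.py` runs 44 subjects × 1200 s
with 20 scramble replicates per scan and a 999-permutation Spearman test.

## Known limitations

* Segmentation constants (threshold, gap closing, maternal veto) are not
  tuned to any real dataset; on real recordings they are the first things to
  revisit.
* Breathing movements carry too little acoustic energy to be detected
  directly at the default SNR threshold — their apparent detection rate is
  mostly chance coincidence, which is visible against the scrambled control.
  This is a property of the acoustic modality, reproduced deliberately.
* The discrimination stage classifies matched ROIs, and on synthetic scans a
  breathing annotation is often matched by a candidate generated by some
  other nearby activity; class separability measured end-to-end is
  therefore conservative for breathing.
* `pca_scope="global"` leaks the held-out row into the transform by design
  (it mirrors a one-shot-PCA protocol); use "fold" for unbiased error
  estimates.
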