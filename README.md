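# fmm — fetal movement detection and discrimination

`fmm` implements the signal-analysis architecture of a wearable fetal
movement monitor: a belt of up to eight low-frequency acoustic sensors on the
maternal abdomen plus a tri-axial accelerometer. The scientific questions the
pipeline answers are (1) can intervals of acoustic activity be isolated as
*candidate fetal movements* while rejecting maternal-motion artefacts, (2) how
often do candidates coincide with movements a physician sees on concurrent
ultrasound, and (3) do the three movement classes — *breathing* (rhythmic,
low amplitude), *general* (whole-body, moderate), *startle* (quick and
vigorous, ~1 s) — differ enough in their signal properties to be told apart.

It is intended for researchers developing or evaluating wearable fetal
movement monitors, who have multi-channel recordings with time-synchronized
observer annotations (or want fully synthetic ones).

## Method

**Segmentation.** Each acoustic channel is comb-notch filtered at the mains
fundamental and harmonics, low-pass de-noised (4th order, 20 Hz; fetal
movement energy sits below ~10 Hz), and reduced to a rectified moving-average
envelope *e(t)*. With noise floor *b* = median *e*, maximal runs with
*e(t) > θ·b* (default θ = 3) become per-channel regions of interest (ROIs),
carrying SNR = mean in-ROI envelope / *b*. Intervals of maternal movement —
high-passed accelerometer magnitude exceeding 0.1 g, padded ±0.5 s — veto
ROIs they cover by ≥ 50 %. Surviving ROIs from all channels are fused
(union, 0.5 s gap closing) into a disjoint candidate-movement timeline.

**Matching.** An observer call-out at time *t* lags the movement, so it is
projected as the tolerance window [*t* − 3.5 s, *t* + 1.5 s). Same-type
call-outs within 5 s first collapse into one movement. An annotation is
*detected* iff its window intersects a candidate; per-type detection rate is
100·detected/observed, and the candidate-to-seen ratio measures false-positive
load. A scrambled-timeline control re-randomizes candidate start times
(durations preserved) to estimate chance-level detection.

**Discrimination.** For each detected annotation the overlapping ROI with the
highest SNR is excised from the *non-rectified* conditioned signal and
summarized by 12 features: duration; energy Σx²; spectral Shannon entropy
(bits); six relative Daubechies-4 wavelet detail-band energies (coarsest six
bands, ≈0.5–32 Hz at 128 Hz); and three periodogram band-energy ratios
(1.1–1.5, 2.2–3, 6–9 Hz, each over the 0.5–20 Hz total). Vectors are
standardized, projected on the first three principal components, and
classified pairwise (breathe/startle, general/startle, breathe/general) by
leave-one-out ("take one out" jackknife) kNN (k = 5; LDA and QDA available),
accumulating 2×2 confusion matrices reported as row percentages.

**Simulator.** `fmm.synthetic` generates seeded multi-channel scans: Poisson
event streams per class rendered as Gabor atoms (startle 3–8 Hz, most
vigorous; general 1–5 Hz; breathing 0.5–1.5 Hz quasi-periodic trains),
distance-attenuated into each channel from random 2-D sources, plus
maternal artefacts visible on the accelerometer, background noise, and an
annotation timeline lagging ground truth by a uniform 0.5–3.5 s reaction
delay. Cohorts draw gestational ages in 24+3–34+6 weeks with a configurable
breathing-rate dependence for Spearman analyses.

## Worked example

```python
from fmm import ScanScenario, simulate_scan, analyze_scan, MovementType

recording, annotations, truth = simulate_scan(ScanScenario(seed=7))
analysis = analyze_scan(recording, annotations)
res = analysis.match_result
for m in MovementType:
    print(f"{m.value:8s} observed {res.n_observed[m]:3d} "
          f"detected {res.n_detected[m]:3d} rate {res.detection_rate[m]:.1f}%")
print("candidates:", res.n_candidates_total)
```

prints

```
breathe  observed  72 detected  22 rate 30.6%
general  observed  25 detected  23 rate 92.0%
startle  observed  16 detected  16 rate 100.0%
candidates: 61
```

i.e. on this 20-minute synthetic scan every vigorous (startle) movement and
nearly every general movement was recovered, while most low-amplitude
breathing movements were not — breathing "detections" are largely chance coincidences
with candidates from other activity, which is exactly what the scrambled
control quantifies.

The same pipeline is scriptable from the shell:

```bash
fmm simulate scenario.toml --out-dir scan1
fmm segment scan1/recording.csv --out-dir seg1 --fs 128 --n-acoustic 6
fmm match seg1/candidates.csv scan1/annotations.csv --out-dir match1 \
    --duration 1200 --scramble 100 --seed 7
fmm discriminate --recording scan1/recording.csv \
    --annotations scan1/annotations.csv --out-dir disc1
fmm run-all --n-subjects 10 --out-dir study --seed 1
```

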