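# Methods

This note documents the models, the synthetic data the package is validated
on, the numerical choices, and the known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal model and processing chain

A subject is a triple of synchronized channels sampled at 125 Hz for 120 s:
one ECG lead, invasive arterial pressure (ABP, mmHg), and a PPG ("PLETH").
Processing is:

1. **Filtering.** PPG: 4th-order Chebyshev type II band-pass, 0.5–10 Hz,
   20 dB stopband (the stopband attenuation is a free design parameter; 20 dB
   keeps the 4th-order transition reasonable at these edges). ECG: 4th-order
   Butterworth band-pass, 0.5–40 Hz. Both are applied forward–backward
   (`sosfiltfilt`): PAT is a timing measurement, and a single-pass IIR group
   delay would bias it by several samples. The raw PPG mean is subtracted
   before the Chebyshev II pass because that filter's equiripple stopband
   does not place a zero at DC; mean removal gives exact DC rejection and a
   small start-up transient. The first and last second of each record are
   excluded from beat extraction to keep residual transients out.
2. **AC/DC normalization.** The filtered PPG (the pulsatile, AC part) is
   divided by the mean of the raw record (the quasi-static, DC part). The
   estimator choice (record mean) makes the output exactly invariant to the
   sensor's overall gain.
3. **Derivatives.** VPG and APG are repeated forward differences scaled by
   the sampling rate (`out[i] = (x[i+1]−x[i])·fs`, last sample replicated to
   preserve length). A forward difference estimates the derivative at the
   midpoint of each sampling interval; tests and the acceptance script
   compare against the analytic derivative at those midpoints, where the
   error at 125 Hz is ~0.01% rather than the ~2.5% a half-sample phase
   offset would masquerade as.
4. **R peaks.** Two-moving-average event detection on the rectified, squared
   filtered ECG: a QRS-scale window (97 ms) against a beat-scale window
   (611 ms) plus an offset of 8% of the mean signal power; candidate blocks
   narrower than half the QRS window are rejected and a 200 ms refractory
   keeps the larger of two close peaks. Window lengths are config keys.
5. **Beats and fiducials.** Beats are R-to-R slices. Within a beat: S is the
   global PPG maximum and O the minimum before it; w is the VPG maximum on
   [O, S] and x the VPG minimum after S; a is the APG maximum on
   [O, w+40 ms], b the APG minimum between a and x, and c, d, e the
   subsequent alternating APG extrema (searched up to 350 ms past x) with a
   prominence floor of 2% of the beat's peak APG magnitude, so micro-wiggles
   that band-pass filtering erases are not counted as landmarks. D is the
   first PPG maximum after S with prominence ≥ 2% of the pulse amplitude and
   N the valley minimum between S and D; single-lobe pulses therefore carry
   no N or D. All landmark times are refined to sub-sample precision by a
   parabola through the three samples around each extremum (125 Hz
   quantization is otherwise the dominant timing error); amplitudes are read
   at the integer extremum sample, so a projected landmark (q₋₁, q₋₂: same
   instant, one/two derivative levels down) has exactly the lower-level
   signal's sample value.
6. **Features.** PAT = t(b₋₂) − t(R), per beat, aggregated per subject by
   the median over beats (robust to occasional detection errors; beats
   missing a required landmark contribute a missing value to that feature
   only, never a zero). The ten morphology features are documented in
   `ppgbp.features`; amplitudes are measured from each level's baseline (PPG:
   the onset value; VPG/APG: zero), power areas are inclusive quadratic sums
   of the normalized PPG. One typeset-ambiguous ratio feature is interpreted
   as the power area from S to the c-projection divided by the full-beat
   (O→next onset) power area; this is an interpretation, recorded here, not
   an externally defined formula.
7. **Labels.** Subject SBP = median over beats of the per-beat maximum of the
   *raw* ABP; categories follow the JNC7 systolic bands with each band's
   lower bound belonging to the higher category (120 → prehypertension,
   140 → hypertension). Thresholds are config keys; diastolic criteria are
   not applied, and stage 1/2 hypertension are merged.
8. **Classification.** Three binary trials (N vs P, N vs H, N+P vs H;
   positive class = the higher-BP category) × three feature sets (PAT,
   PPG10, PAT+PPG10) × four families (AdaBoost with 50 depth-1 trees,
   L2 logistic regression, KNN with K=5 on standardized Euclidean distance,
   bagging with 100 trees). Stratified 70/30 split (unstratified splits can
   starve a 34-subject class), standardization fitted on the training
   portion only, 10-fold CV on the training portion (folds reduced to the
   smallest class count when necessary), refit, test-set metrics. Because a
   single split of ~121 subjects is high-variance, grids are repeated over
   split seeds and summarized as mean ± SD.

## The synthetic cohort

Real ICU archives provide no landmark-level ground truth, so validation uses
generated records in which every quantity the detectors recover is known by
construction.

**Pulse template.** A sum of compactly supported squared-Hann (cos⁴) lobes:
a systolic lobe peaking `systolic_width` (default 0.16 s) after onset, a
dicrotic lobe of relative amplitude `dicrotic_amplitude` (0.45) peaking
`dicrotic_delay` (0.26 s) after the systolic peak, and a notch carving
`notch_depth` (0.5) of the inter-lobe valley floor (the notch amplitude is
bounded by the valley minimum over its support, which provably keeps the
waveform non-negative). Compact support makes the inter-beat baseline
exactly zero — so the noise-free ABP maximum/minimum equal SBP/DBP exactly —
and the C² lobe edges keep APG landmarks interior smooth extrema whose
positions are stable under filtering. Per-subject, per-class defaults:

| parameter | default | shift per class (× class_effect) | rationale |
|---|---|---|---|
| systolic_width (s) | 0.16 | +0.012 | slower upstroke with stiffer vessels |
| dicrotic_amplitude | 0.45 | −0.10 | damped diastolic wave |
| dicrotic_delay (s) | 0.26 | −0.025 | earlier wave reflection |
| notch_depth | 0.5 | −0.15 | shallower notch |

with 6% relative per-subject jitter; `class_effect = 0` gives identical
morphology distributions across classes (the null condition).

**Timing.** R times start at 0.5 s with beat-period jitter of CV 2% (so beat
segmentation is non-trivially exercised); heart rate is drawn N(70, 6) bpm
clipped to [55, 80] — the upper clip guarantees the pulse support plus the
longest PAT fits inside one R–R interval. The ECG is a train of 10 ms-sigma
Gaussian R spikes: only R timing is consumed downstream, so P-QRS-T realism
would add nothing the pipeline reads. PPG onsets trail each R by
`pat_true = 0.47 − 0.0015·SBP + ε` seconds (≈0.33 s at SBP 96 down to
≈0.20 s at 180), with ε ~ N(0, 0.03 s) emulating imperfect ECG–PPG
synchronization in archived records; this places the PAT-only classifier in
a weak-but-informative regime while morphology remains the stronger signal,
the regime the analysis is designed around. SBP is drawn uniformly within
each category band (96–119 / 120.5–139.5 / 140.5–180 mmHg; half-point
margins keep noise-free labels unambiguous), DBP = 0.62·SBP + N(0, 2). The
ABP pulse reuses the template scaled to [DBP, SBP] with each systolic peak
snapped onto the sampling grid so the noise-free maximum is exact. Additive
white noise (default 3% of pulse amplitude) and 0.25 Hz baseline wander (5%)
model measurement disturbance; pathological rhythms, motion artifacts and
sensor drop-outs are not modeled.

**What passing shows.** Recovery and ordering results on these cohorts
validate the *chain* — that detectors find what is present, that features
compute their formulas, that no information leaks across the train/test
boundary — under clean, unimodal, artifact-free pulses. They do not certify
performance on real ICU data, where signal quality, arrhythmias, medication
effects and sensor asynchrony are harsher than anything the generator emits.

**Ground-truth oracle.** Template landmark truth times are computed on a
densely sampled (4 kHz) noise-free template with plain extremum searches and
the same 2% prominence floor — independent of the 125 Hz detection pipeline.
Fiducial-recovery checks compare detected times per beat against these
truths with a ±2 sample (16 ms) budget.

## Study sizes used by tests and the acceptance script

Chosen as the smallest sizes that exercise each property convincingly:
fiducial recovery on a 10-subject noise-free cohort (~1,300 interior
beats); PAT recovery on 30 subjects with SBP evenly spaced over 96–180 mmHg
(even spacing makes exact rank agreement a meaningful criterion — with
random SBP draws two subjects can be closer in true PAT than any detector
could resolve); the null control on 20+20 subjects over 20 split seeds; and
the full-size 46/41/34 cohort over 25 split seeds for the feature-set
ordering. All records are full-length (120 s) except where a test only
exercises I/O or smoke paths.

## Known limitations

* The fiducial taxonomy assumes a two-lobe pulse; pulsus bisferiens and
  heavily damped waveforms will mislabel c/d/e, which is why per-subject
  aggregation is a median and beats with missing landmarks are dropped
  rather than imputed.
* The notch-depth default produces a deeper notch (valley near baseline)
  than typical adult PPG; detection does not depend on notch depth, but
  absolute values of notch-adjacent features should not be compared to
  clinical tables.
* The WFDB-style reader/writer supports only format 16 with a gain/offset
  header — enough for round-tripping this package's records, not a general
  archive client.
* At 125 Hz, landmark timing below one sample relies on parabolic
  interpolation, which assumes locally quadratic extrema; very sharp
  artifacts violate that assumption.
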