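# ppgbp

Cuffless hypertension-category assessment from simultaneously recorded
ECG, invasive arterial blood pressure (ABP), and photoplethysmogram (PPG)
waveforms.

## The problem

Hypertension is largely symptomless, so screening methods that work from
signals a wearable can record — an ECG lead and a pulse-oximeter PPG — are
of real clinical interest. Two physiological routes connect these signals
to blood pressure:

* **Arterial wave propagation.** The pressure pulse travels faster in a
  stiffer (higher-pressure) arterial tree, so the **pulse arrival time
  (PAT)** — from the ECG R peak to a landmark on the same heartbeat's PPG
  upstroke — shortens as systolic pressure rises. This package uses the
  "PAT-middle" convention: the interval from R to *b*₋₂, the PPG read at
  the instant of the acceleration waveform's b wave (mid-upstroke).
* **Pulse morphology.** Vascular stiffness and peripheral resistance
  reshape the PPG pulse: the dicrotic notch and diastolic wave, the
  relative timing of the systolic peak, and the a–e wave pattern of the
  second derivative (APG) all shift with BP level.

The package implements the full analysis chain: band-pass filtering
(Chebyshev II 0.5–10 Hz for PPG, Butterworth 0.5–40 Hz for ECG, both
zero-phase), AC/DC normalization, forward-difference velocity (VPG) and
acceleration (APG) waveforms, R-peak detection by a two-moving-average
event detector, beat-by-beat landmark location (O, S, N, D on the PPG;
w, x, y, z on the VPG; a–e on the APG, with −1/−2 projections), PAT plus a
ten-feature morphology vector per subject (median over beats), JNC7
systolic labeling from the raw ABP (normotension < 120 mmHg ≤
prehypertension < 140 mmHg ≤ hypertension), and a classification study:
three binary trials × three feature sets (PAT, PPG10, PAT+PPG10) × four
classifier families (AdaBoost stumps, logistic regression, KNN, bagged
trees) with a stratified 70/30 split and 10-fold CV on the training
portion, reporting sensitivity, specificity, precision and
F1 = 2·Recall·Precision/(Recall+Precision).

Because ICU waveform archives publish no per-record ground truth, the
package ships a synthetic cohort generator whose records carry exact
R times, pulse onsets, true PAT, true SBP, and category labels, so every
detector in the chain can be validated against construction-time truth.
See `docs/methods.md` for the model details and design choices.

## Worked example

```bash
ppgbp all --n-normo 46 --n-prehyp 41 --n-hyp 34 --seed 7 --out results/
```

generates a 121-subject cohort (120 s per subject at 125 Hz), extracts the
labeled feature table (`results/features.csv`), and runs the trial grid
(`results/results.csv`, `results/summary.csv`). The same study from
Python:

```python
from ppgbp import generate_cohort, build_feature_table, run_trials

records = generate_cohort(46, 41, 34, class_effect=1.0, seed=7)
table = build_feature_table(records)
print(table[["subject_id", "label", "sbp", "pat", "f9"]].head(3))
results = run_trials(table, seeds=range(25), classifiers=("knn",))
print(results.groupby(["trial", "feature_set"])["F1"].mean().round(3))
```

prints (values from an actual run):

```
  subject_id         label         sbp       pat        f9
0       S000  normotension  110.396181  0.426164 -0.155673
1       S001  normotension  106.758200  0.456503 -0.053475
2       S002  normotension  114.224846  0.393603 -0.143040
```

```
trial    feature_set
NP_vs_H  PAT            0.568
         PAT+PPG10      0.945
         PPG10          0.912
N_vs_H   PAT            0.711
         PAT+PPG10      1.000
         PPG10          0.976
N_vs_P   PAT            0.458
         PAT+PPG10      0.926
         PPG10          0.907
```

Read: each `pat` is the per-subject median R→b₋₂ interval in seconds
(longer in normotensives), `f9` is the APG d/a ratio (more negative with
higher BP), and the F1 table shows the study's qualitative finding — PAT
alone is a weak classifier, the ten morphology features are strong, and
adding PAT to them improves every trial, with normotension-vs-hypertension
the easiest separation.

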