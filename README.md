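# gaitrisk

Wearable-sensor gait analysis and retrospective fall-risk classification
for older adults.

Falls are the leading injury cause in people over 65, and half of them
happen while walking. `gaitrisk` implements a point-of-care style
analysis pipeline for classifying older adults as fallers or non-fallers
from a short instrumented walk: pressure-sensing insoles (total vertical
force and centre-of-pressure path at 120 Hz, per foot) and tri-axial
accelerometers at the head, pelvis and both shanks (50 Hz), recorded
under single-task (ST) and dual-task (DT, concurrent verbal fluency)
conditions, optionally alongside seven clinical assessment scores (ABC,
CHAMPS frequency/calories, 6MWT distance, ST/DT walk times, fear of
falling). It is aimed at movement-science and biomedical-engineering
researchers who want a tested, reproducible implementation of this
feature set and model-comparison procedure — including a synthetic-data
generator, because raw cohort recordings of this kind are rarely shared.

## What it computes

**30 plantar-pressure parameters** per trial: centre-of-pressure (CoP)
path irregularities — counts, mean lengths and durations of posterior
deviations (runs of posterior CoP motion) and of mediolateral deviations
(|ΔCoP_ML| > 0.5 mm/frame); min/max/mean/median CoP path velocity
normalised by stance time; ensemble AP/ML CoP variability over 101
stance-normalised points, CoV% = 100·√(mean σᵢ²)/mean|μᵢ| (Winter's
formulation); temporal gait parameters (cadence, stride/stance/swing
time, %stance, %double support, double-support time, stride-time
symmetry index SI% = 100·|L̄−R̄|/(½(L̄+R̄)), stride-to-stride CoVs); and
impulses I1–I7, trapezoidal ∫F dt over stance sub-phases bounded by foot
strike, the two force peaks, the mid-stance minimum and foot off,
normalised by body mass (N·s/kg), with I5=I1+I2, I6=I3+I4, I7=I5+I6.

**29 accelerometer parameters** per body site: max/mean/SD of
acceleration magnitude per directional half-axis (superior, inferior,
anterior, posterior, right, left); cadence and stride time from
vertical-axis peak timing; the FFT quartile (% of spectral content at
f ≤ 12.5 Hz) per axis; the ratio of even to odd harmonics of stride
frequency (REOH) per axis; and the maximum Lyapunov exponent per axis by
Rosenstein's method, with the embedding delay from the first minimum of
the average mutual information and the dimension from global false
nearest neighbours. Descriptive statistics and MLE use the 5th-order
12.5 Hz zero-phase Butterworth output; FFT quartile and REOH use the raw
signal.

**Classification and ranking.** All 31 sensor combinations (insole
and/or any subset of the four accelerometers; 29–146 input parameters)
plus the clinical set are trained with three model families —
single-hidden-layer perceptrons (5–25 nodes, plus refinement between the
best node count and its better neighbour), linear/quadratic Gaussian
naive Bayes, and polynomial SVMs of degree 1–7 — on a stratified 75/25
participant split. Each model is scored with accuracy, sensitivity,
specificity, PPV, NPV,

    F1  = 2·TP / (2·TP + FP + FN)
    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

and models are compared by ranking every metric across models (1 = best,
ties share the mean rank) and summing the seven ranks; the lowest summed
rank wins. A useful benchmark: on a 24-faller/76-non-faller cohort the
constant "everyone is a non-faller" classifier scores 76% accuracy with
F1 = 0 and MCC = 0.

## Worked example

Reconstruct the confusion matrix implied by a reported model row —
sensitivity 50.0%, specificity 94.7% on a held-out set of 6 fallers and
19 non-fallers — and recompute its metrics:

```python
from gaitrisk import confusion_from_rates, compute_metrics

cm = confusion_from_rates(6, 19, sensitivity_pct=50.0, specificity_pct=94.7)
print(f"confusion matrix: TP={cm.tp} FP={cm.fp} FN={cm.fn} TN={cm.tn}")
m = compute_metrics(cm)
print(f"accuracy {m.accuracy_pct:.1f}%  PPV {m.ppv_pct:.1f}%  NPV {m.npv_pct:.1f}%")
print(f"F1 {m.f1:.3f}  MCC {m.mcc:.3f}")
```

prints

```
confusion matrix: TP=3 FP=1 FN=3 TN=18
accuracy 84.0%  PPV 75.0%  NPV 85.7%
F1 0.600  MCC 0.521
```

i.e. that model caught 3 of the 6 fallers at the cost of one false
alarm; the MCC of 0.52 places it well above chance (MCC 0) on a test set
this small.

The full pipeline runs from the shell. Generate a synthetic cohort,
extract every gait parameter, and rank models for single-task walking:

```bash
gaitrisk simulate --config cohort.yaml --seed 4 --out cohort/
gaitrisk extract  --cohort cohort/ --out features.csv
gaitrisk rank     --features features.csv --labels cohort/labels.csv \
                  --condition ST --combinations all --seed 2 --out report.csv
```

`report.csv` has one row per (sensor combination, model), with the seven
metrics and the summed rank, sorted best first. With the default
synthetic effect sizes the groups are strongly separable, so top models
typically reach 90–100% held-out accuracy; with `effects` set to zero
shifts, MCC collapses to chance level — both behaviours are asserted in
the test suite.

## Layout

- `src/gaitrisk/synthetic.py` — cohort/trial generator with configurable
  faller effect sizes (the defaults are invented, directionally standard
  values; no per-group gait distributions exist to copy)
- `src/gaitrisk/io.py` — trial CSV formats, sensel-grid → CoP reduction,
  zero-phase Butterworth filter
- `src/gaitrisk/events.py` — stance segmentation (5% body-weight force
  threshold) and accelerometer stride detection
- `src/gaitrisk/insole.py`, `src/gaitrisk/accel.py` — the 30 + 29-per-site
  gait parameters
- `src/gaitrisk/classify.py` — sensor combinations, model sweeps, metrics,
  rank-sum comparison
- `docs/methods.md` — modelling assumptions, parameter defaults, and
  known limitations
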