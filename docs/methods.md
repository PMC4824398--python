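# Methods

This note documents the models, parameter choices and known limitations
behind `gaitrisk`. It is written for a reader who wants to judge what
the pipeline's outputs — and its passing tests — do and do not
establish.

## The synthetic cohort generator

No raw recordings of this kind are publicly deposited, so every stage of
the pipeline is exercised against a generative model with exact ground
truth. The generator is deliberately a *signal* model, not a
biomechanical one: it reproduces the statistical structure the feature
definitions rely on, with parameters a feature should recover known in
closed form.

**Stride clock.** Both feet share a common sequence of stride onsets;
stride durations are i.i.d. normal with mean `stride_time_mean_s`
(default 1.05 s non-fallers / 1.12 s fallers) and coefficient of
variation `stride_time_cv_pct` (2% / 4%), truncated to ±50% of the mean.
The right foot strikes half a stride after the left. Dual-task trials
multiply the CoV by 1.5 and the mean stride time by 1.05 — a
deteriorated, more variable gait under cognitive load.

**Insole streams (120 Hz).** During each stance (duration =
`stance_fraction` × stride, defaults 0.620 / 0.645, split ±asymmetry/2
between feet) the total vertical force follows
`F(τ) = 1.15·m·g · sin(πτ)(1 + 0.4·cos 2πτ)` (normalised to its peak),
a double-bump curve with two force peaks and a mid-stance valley, zero
in swing. The CoP advances linearly from 30 mm to 210 mm (insole frame,
AP positive anterior) during stance, with a smooth ±2 mm ML sway whose
per-frame derivative stays below the 0.5 mm/frame deviation threshold.
Irregularities are injected as non-overlapping square pulses with known
count (Poisson with mean `pd_per_stance` / `ml_dev_per_stance` per
stance), width (3 frames at −1 mm/frame posterior; 2 frames at
±0.8 mm/frame ML) — so deviation counts, lengths and durations have
exact expected values. CoP samples are flagged invalid wherever force is
below 5% body weight.

**Acceleration streams (50 Hz).** Each axis is a harmonic series at the
instantaneous stride frequency (phase integrated through the varying
stride durations): amplitude of harmonic k = 2·scale·w_k·h for even k
and 2·scale·w_k·(1−h) for odd k, with template weights w = (0.5, 1.0,
0.35, 0.45, 0.15, 0.2) for k = 1..6, per-site/axis scales between 0.6
(head ML) and 3.0 m/s² (shank vertical), and random phases.
`harmonic_purity` h (0.72 / 0.58) therefore sets the even-harmonic share
and monotonically drives the downstream REOH. A ±30% amplitude
modulation at stride frequency makes the two steps of a stride
distinguishable, as left and right steps are in real signals. White
noise of SD `noise_sd` (0.15 / 0.35 m/s²) is added per axis.

**Clinical features** are truncated normal draws with faller shifts in
the conventional directions (lower balance confidence and activity,
shorter 6MWT, slower walks, higher fear); the 6MWT and body-mass
parameters use the published cohort means/SDs, the rest are invented.
The dual-task walk time is the single-task time plus a non-negative
dual-task cost, so DT ≥ ST holds in expectation.

**What the generator does not emulate**: sensel-level pressure images,
gravity leakage and orientation drift in accelerometers, turning,
non-stationarity across a trial, and any genuine physiological coupling
between parameters (each is drawn independently). Consequently, a
classifier separating synthetic fallers from non-fallers shows the
*pipeline* preserves the injected group differences — it says nothing
about how separable real cohorts are. All default effect sizes are
invented: no per-group distributions for these gait parameters are
published, so the defaults are labelled as such and exposed in
`effect_config`.

**Missing sensors.** An option reproduces the sensor power failures of
the emulated study (pelvis stream absent for two non-fallers, left shank
for one); it is off by default so the canonical 24/76 → (18, 57)/(6, 19)
split holds on complete cohorts.

## Signal processing choices

- **Filtering** is a 5th-order low-pass Butterworth at 12.5 Hz, applied
  forward–backward (zero phase). Temporal features are extracted after
  filtering, and a causal filter's group delay would bias event timing;
  phase handling is therefore fixed to zero-phase. Descriptive
  statistics and the Lyapunov exponent consume the filtered signal; FFT
  quartile and REOH consume the unfiltered signal.
- **Stance detection** thresholds total force at 5% body weight (a
  conventional stance-detection level, configurable), discards
  supra-threshold runs shorter than 0.1 s as noise and partial contacts
  at the recording edges. Because the threshold is relative to body
  weight, detection is invariant to joint force/mass scaling. On
  noise-free synthetic trials detected events sit within one frame of
  ground truth (the force ramp crosses 5% BW in under one 120 Hz frame).
- **Accelerometer stride detection** estimates the stride period from
  the autocorrelation of the filtered vertical axis (smallest lag in
  0.4–4 s reaching 95% of the band maximum) and takes peaks with a
  minimum separation of 0.6 stride periods. A minimum separation tied to
  the *median inter-peak interval* was rejected: when even (step)
  harmonics dominate — the common case for vertical acceleration — that
  rule locks onto the half-stride period and halves every stride time.
  The same detector is used for all four sites; no published choice of
  axis or method exists to follow.
- **Double support** is computed from the bilateral overlap of stance
  intervals assuming the two insole streams share a synchronized clock
  (the generator guarantees this; hardware alignment is out of scope).

## Feature definitions: resolved ambiguities

- **The 30-parameter enumeration.** The insole set is fixed as 12 CoP +
  11 temporal + 7 impulse features. The temporal family's printed
  enumeration yields only ten; absolute double-support time is included
  as the eleventh (the natural companion of percent double support) to
  reach the documented total of 30. This is a reconstruction, marked as
  such.
- **"Velocities normalised by stance time."** CoP path velocity is
  already a rate, so the phrase is ambiguous; each stance's velocity
  statistic is divided by that stance's duration (mm/s per s), with a
  switch (`normalize_by_stance_time=False`) to disable.
- **Posterior vs ML deviation thresholds.** Posterior deviations count
  *any* frame-to-frame posterior (negative AP) step; the ±0.5 mm/frame
  dual threshold applies to ML only — the two rules are stated
  separately in the source description. The ML threshold is nominally
  tied to a 120 Hz frame and exposed in config.
- **Ensemble CoV** uses population (ddof=0) SDs across stance traces at
  each of 101 stance-normalised points: CoV% = 100·√(mean σᵢ²)/mean|μᵢ|.
  Stride-to-stride CoVs of temporal features use sample SD (ddof=1), the
  convention for gait-variability reporting.
- **Impulse landmarks** (first peak, mid-stance minimum, second peak)
  are located on a 10 Hz low-pass copy of the stance force curve to
  suppress sensel noise; integration uses the raw curve. Stances without
  a double bump contribute only to I7; if more than half fail, I1–I6 are
  reported missing for the trial.
- **Aggregation**: per-stance values are pooled across both feet's
  stances and averaged, matching a combined-limb summary.
- **FFT quartile** is the percentage of summed spectral *magnitude* (a
  `power` mode is available) at 0 < f ≤ 12.5 Hz relative to all positive
  frequencies, DC excluded. At a 50 Hz sampling rate 12.5 Hz is half of
  Nyquist; the stated cut-off is followed as given.
- **REOH** sums harmonic magnitudes (nearest bin ±1) at k× stride
  frequency for k = 1..20 (capped below Nyquist):
  ΣA_even/(ΣA_even+ΣA_odd). The harmonic count and ±1-bin peak search
  follow common harmonic-ratio practice and are configurable.

## Nonlinear dynamics (MLE) stack

The per-axis maximum Lyapunov exponent uses Rosenstein's method: delay
embedding (delay from the first local minimum of the 16-bin histogram
AMI over lags 1–50; dimension from Kennel's global FNN with rtol 15,
atol 2, 1% threshold, max dimension 6), nearest neighbours constrained
to temporal separation greater than the mean period (from the
power-weighted mean frequency), mean log divergence tracked over a fit
window of half the mean period, and the least-squares slope converted to
1/s. Exact-duplicate embedded states (which arise when a periodic signal
is sampled commensurately) are excluded from neighbour search — their
log-divergence measures only rounding noise — and treated as true
neighbours in FNN unless the added coordinate separates them.

Validation anchors: the r=4 logistic map (analytic exponent ln 2 per
step) is recovered within 10% at 5,000 samples by the full
AMI→FNN→Rosenstein chain; a pure sine yields |MLE| below 5% of that
value; the Lorenz-x series embeds at dimension 3±1; white noise never
embeds and falls back to the maximum dimension with a warning.

Two caveats are deliberate:

- Binned AMI on *noiseless* commensurately-sampled sines shows shallow
  spurious minima (an artifact of equal-width binning of the arcsine
  density, independent of sample count), so the delay can land below the
  quarter period. Real and synthetic accelerations contain noise, which
  removes the artifact; the unit test uses a lightly noisy sine for the
  same reason.
- The monotone response of the estimated MLE to the generator's noise
  level is verified at a *fixed* embedding (delay 12, dimension 5):
  under the adaptive chain, FNN selects different dimensions at
  different noise levels (noise never embeds), which confounds the
  trend. The trial-level features keep the adaptive chain, as the
  analysis procedure prescribes; their absolute values should be read as
  method-specific indices, not attractor invariants. Normalisation is
  per second; per-stride normalisation would divide by stride time.

## Classification stage

- Features are z-scored on training-set statistics before model fitting
  (distance- and kernel-based learners require comparable scales; a
  switch disables it). Missing values are mean-imputed on training
  statistics; participants missing an entire required sensor block are
  excluded from that combination instead.
- The 75/25 split is stratified by label with floor-based per-class
  training counts, so 24/76 yields exactly (18, 57) train and (6, 19)
  test.
- "Linear" naive Bayes is Gaussian NB with a pooled (class-shared)
  diagonal covariance — the log-odds are then linear in the features;
  "quadratic" is the per-class-covariance variant (scikit-learn's
  `GaussianNB`). This is the closest standard reading of a
  linear/quadratic naive-Bayes pair.
- SVMs use polynomial kernels of degree 1–7 with `gamma="scale"`,
  `coef0=1`, `C=1`. Perceptrons have one hidden layer (5–25 nodes, step
  5); after the base sweep, if the best node count's better-performing
  neighbour exists, the intermediate node counts are also evaluated
  (e.g. best 15 with 20 beating 10 adds 16–19). Best-ness within the
  sweep is judged by accuracy, then MCC. Each (combination, model) pair
  gets a fixed seed derived from the base seed by hashing, so runs are
  reproducible model-by-model.
- Ranking: each of the seven metrics is ranked across all evaluated
  models (rank 1 best; ties share the mean of covered ranks — the tie
  rule is not documented in the source, mean-sharing is the standard
  choice), and ranks are summed. Models are ranked on unrounded metric
  values across the full evaluated set, and output ties are broken by
  accuracy, then MCC, then name, to make the ordering deterministic.
- Zero-denominator conventions: sensitivity, specificity, PPV, NPV, F1
  and MCC are defined as 0 when their denominator vanishes, consistent
  with the constant-non-faller baseline scoring F1 = 0 and MCC = 0.

## Problem sizes used in the test suite

End-to-end checks run at sizes chosen for a single CPU: the separability
check uses one 24/76 cohort (single-task, 10 s trials ≈ 8–12 strides per
foot) with the full 31-combination sweep; the chance-level check uses 20
seeds of 15/45 pelvis-only cohorts, scoring one fixed model (SVM-2) per
seed and asserting the median held-out MCC lies in [−0.15, 0.15].
Scoring the best-of-sweep model instead would bias that median upward
purely by test-set selection. Trials of 10 s are shorter than a 6-minute
walk but long enough for every feature (≥ 6 strides; ≥ 100 embedded
points for the MLE).

## Known limitations

- Synthetic trials are stationary and turn-free; real 7.62 m walks
  include gait initiation and termination transients that the event
  detector would include unless trimmed upstream.
- The CoP is generated and analysed in the insole frame with AP positive
  anterior; foot-referenced coordinates would change CoP magnitudes but
  not the deviation/variability logic.
- MLE values on ~500-sample trial segments are short-series estimates
  with large variance; they are comparable within a fixed protocol, not
  across protocols.
- The generator's effect sizes are configuration, not estimates;
  classification accuracies on synthetic cohorts characterise the
  pipeline, not any real population.
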