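# Methods

## Problem and signal model

The package detects periods of talking from the respiratory signals of
three resistive stretch bands (upper chest, lower chest, abdomen).
Breathing expands the torso, stretches the sensors and raises their
resistance; the acquisition chain is a voltage divider — a 5 V DC source
in series with a 20 kΩ reference resistor matched to the sensor's base
resistance — sampled at 100 Hz. The measured voltage is taken **across
the sensor** (reference resistor on the source side), a convention fixed
package-wide:

    v = V_s · r / (R_ref + r)        r = R_ref · v / (V_s − v)

Either tap placement would be defensible; the package documents one and
uses it consistently, so the forward model and its inversion are exact
inverses (verified to 1e−9 relative error).

Speech breathing differs from quiet breathing in morphology: a fast
inhalation (tenths of a second) followed by a long, slow, irregular
exhalation that sustains phonation. Quiet resting breathing is rhythmic
at 12–18 cycles/min with near-balanced phases. The classifier learns
this contrast from windowed signal features.

## Synthetic recordings

Real recordings of this kind are not publicly available, so the
simulator is a first-class module generating annotated data with the
structure the detector assumes. What it emulates:

* **Breath cycles** as piecewise half-cosines: a rise from baseline to
  the cycle amplitude over the inhale duration, a fall back over the
  exhale duration. The half-cosine is band-limited and lets the
  inhale/exhale asymmetry be set independently — a sinusoid cannot
  express it.
* **Quiet preset**: inhale 1.9 s, exhale 2.1 s (15 cycles/min, the middle
  of the physiological 12–18 band), amplitude 10 kΩ, duration/amplitude
  CV 5%.
* **Speech preset**: inhale 0.55 s, exhale 4.0 s (≈13 cycles/min —
  longer cycles because of the long exhale), amplitude 12 kΩ, CV 25%
  (irregularity is part of the speech signature). No published numeric
  characterization of speech-breathing rate or amplitude for this sensor
  exists; these are explicit package defaults, chosen once.
* **Block protocol**: per trial one 120 s non-talk block then one 120 s
  talk block, five trials per activity — one hour per participant at the
  defaults, with talk intervals recorded as ground-truth annotations.
* **Channel structure**: the three bands share breath timing (one
  diaphragm drives them all) but have independent gains (defaults 1.0,
  0.8, 0.6 — upper chest dominant), independent noise (Gaussian,
  SD 0.1 kΩ), independent sinusoidal baseline drift (amplitude 2 kΩ,
  period 60 s, random phase) and independent movement artifacts.
* **Movement artifacts**: random-time, random-sign exponential-decay
  transients (mean height 5 kΩ, decay 0.8 s) at an activity-dependent
  Poisson rate — sitting 0, standing 2, walking 6 events/min — mimicking
  bending/rotation disturbances that grow with activity intensity.
* **Acquisition**: resistance is clipped at 0 (physical), pushed through
  the divider, and returned as voltage — exactly what a DAQ would record.

What it does **not** emulate: sensor hysteresis and temperature drift,
chest-vs-abdominal breather heterogeneity beyond static gains,
conversational pausing inside talk blocks, posture changes, or any
coupling between talking and movement artifacts. Passing tests therefore
demonstrate the pipeline's correctness and its ability to recover a
known morphology contrast — not field performance on real torso
recordings, where accuracies in the mid-80s percent are realistic rather
than the near-perfect synthetic numbers.

Determinism: one `numpy` Generator seeded from `SimulationConfig.seed`
drives every draw, so identical configs give bit-identical recordings.

## Filtering and breath detection

4th-order Butterworth bandpass, 0.1–1.5 Hz. The cutoffs are the
half-power (−3 dB) frequencies of a single pass (the standard Butterworth
convention; the digital design places them exactly). By default the
filter runs forward and backward: zero net phase — peak times must not
shift relative to the talk annotations — at the cost of doubled
attenuation, which is irrelevant this deep in the stop bands.

Peaks are selected by topographic prominence (height above the higher of
the two lowest valleys separating the peak from any taller sample) with
a minimum of 5 kΩ on the filtered resistance signal. The threshold's
units are a package decision: "5" is meaningful only relative to a
signal scale, and the simulator's breath amplitudes (10–12 kΩ, roughly
doubled peak-to-valley after bandpass) make 5 kΩ an effective floor
against noise and drift residue. Plateau maxima report their leftmost
sample. Detection runs per channel; the downstream event stream is the
union across channels, each event tagged with its channel, so feature
selection can discover which bands are informative.

A 3-s analysis window is centred on each peak; a breath is labelled
*talking* iff its peak time lies in an annotated talk interval (half-open
`[start, end)`). Peaks closer than 1.5 s to a recording edge are
dropped.

## Features

Thirteen families on six series per breath (3 bands × {raw window, first
difference}), 288 features per event. Parameter defaults beyond the
fixed r = {1, 2} (tail ratios), N = 10 (energy chunks) and m = 0
(crossings):

| family | parameters | rationale |
|---|---|---|
| Fourier coefficients | first 10 rFFT bins, real+imag | covers 0–3.3 Hz of a 3-s window |
| Welch density | power at bins 2, 5, 8; nperseg = min(n, 256) | standard periodogram summary bins |
| CWT peaks | Mexican-hat scales {1, 2, 5, 10} samples, peaks with prominence ≥ 0.1 × row range, summed | multi-scale transient count with an explicit, oracle-checkable rule |
| sample entropy | m = 2, r = 0.2 · SD | canonical regularity settings; SD-relative r makes it scale-invariant |
| AR coefficients | order 4, conditional least squares (`AutoReg`) | low-order dynamics of a 300-sample window |
| ADF | fixed max lag 4, no automatic lag search | deterministic and fast; the statistic (not the p-value) is the feature |
| symmetry | \|mean − median\| < 0.25 × range | boolean distribution-symmetry flag |

Sample entropy is computed with an incremental Chebyshev distance-matrix
recursion (exact, O(m·n²) vectorized) and is verified against a naive
template-matching oracle; both use the Richman–Moorman convention
(both counts over the first n−m templates, self-matches excluded). A
degenerate input (zero variance, too short) yields NaN, and NaNs are
imputed with training-set medians — fitted on training data only, so no
information crosses the evaluation boundary.

Selection: a 100-tree random-forest ranker per stratified fold, Gini
importances averaged across folds, top 10% of names kept
(ceil, ties broken by name) — deterministic given the seed.

## Classification and evaluation design

Four families with fixed hyperparameters: random forest (200 trees),
RBF-SVM (γ = 0.01, C = 10; Platt-scaled probabilities), MLP (2 hidden
layers × 30 neurons, max 500 epochs, seeded initialization), LDA. SVM
and MLP inputs are z-scored with training-fold statistics; trees and LDA
are scale-robust and take raw features. Scores are class-1 probabilities
in [0, 1]; hard labels threshold at 0.5 (no operating-point tuning).

Cross-validation is stratified 15-fold with pooled out-of-fold scores
forming one ROC (trapezoidal AUC). **Folds are grouped by physical
breath**: one inhalation raises peaks on up to three bands, producing
near-duplicate events whose feature vectors all span all three channels.
If plain stratified folds split such duplicates across train and test, a
flexible learner memorizes breath identity — in a control experiment
with the speech morphology set equal to the quiet one (no class signal
at all) ungrouped CV scored ≈99% accuracy where chance (≈50%) is the
only honest answer. Events whose peak times lie within 1 s of each other
(well under a breath cycle) share a group, and `StratifiedGroupKFold`
keeps groups intact. With grouping the no-signal control sits in the
chance band and the default-morphology pipeline still exceeds 0.85 AUC.

A temporal 70/30 split utility (first ⌈0.7·n⌉ time-ordered events train)
supports held-out evaluation; the pipeline default cross-validates each
participant × activity subset, training one model per activity.

Metrics: ACC, TPR, FPR as percentages from the confusion counts with
talking positive; a zero denominator makes a metric explicitly undefined
(`None`, rendered "NA"), never silently 0. Segment accuracy is computed
over true talking segments only: correct iff strictly more than half of
the member breath predictions say talking — an exact tie, or a segment
with no detected breaths, counts incorrect (the conservative reading of
"majority"). Report tables give mean (sample SD) per activity plus an
overall row, and a per-participant breakdown.

## Orchestration, sizes, reproducibility

`run_experiment` derives every stage seed as
`sha256(global_seed:stage)[:4] mod 2^31`, so stages are independently
and reproducibly seeded; reruns are byte-identical. Intermediate
artifacts (recording CSV, feature matrix, reports) are written per
participant × activity and are reloadable through the same I/O module.

Problem sizes used by the test suite are deliberate package choices that
keep a laptop run comfortable: the simulator-vs-detector rate check uses
a 10-minute quiet recording; the signal-recovery and chance-band
experiments use 3 trials (720 s, ≈500 breath events) per recording; the
classifier-comparison check uses a single-trial recording. The full
5-trial protocol runs through the same code paths via the CLI.

## Known limitations

* Simulator realism bounds all conclusions: no hysteresis, no real
  inter-subject variability, artifacts independent of the breath signal.
* The prominence threshold's published value is unitless; our kΩ
  interpretation is calibrated to the simulator's amplitude scale and
  would need re-calibration against real sensor gains.
* Feature-family parameters pin one explicit configuration rather than
  sweeping hundreds of automated variants; ranking among classifier
  families on synthetic data need not transfer to real recordings.
* The ADF and AR features use fixed-lag least-squares fits; exact
  unconditional maximum-likelihood AR estimation is not exposed by the
  current statsmodels API and the conditional fit is used instead.
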