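# Methods

This note documents what the package computes, the models behind its
synthetic data, the numerical choices, and what the tests do and do not
establish.

## The analysis

The pipeline classifies the presence/absence of four causes of a hazardous
driver state — cell-phone use, sleep deprivation (drowsy sessions), high
traffic density (town), poor weather (snow) — from three feature blocks
extracted over 4-minute scenarios of a within-subject factorial driving
study. The default design is 21 participants × 4 sessions (exactly 2
drowsy) × (1 baseline + 8 scenarios), the 8 scenarios enumerating every
(traffic, weather, phone) combination in seeded random order: 672 scenario
samples.

### Features (61 per scenario)

* **Physiology (17)** — respiration: mean rate (breaths/min), rate std over
  1-minute windows, RMSSD of breath periods (s); skin temperature: mean and
  last-second-minus-first-second difference; skin conductance: tonic mean
  and first/last-second difference, SCR count and amplitude mean/std (µS);
  ECG: mean HR, IBI std, median and mean-absolute first difference of the
  filtered ECG, LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz) band powers of the
  IBI spectrum and their ratio.
* **Kinematics (24)** — mean, std and fluctuation (mean |first difference|)
  of throttle, lane number (0/1), lateral lane position, road offset,
  longitudinal and vertical velocity, front and rear tire slip.
* **Characteristics (20)** — age, gender, dominant hand, driving
  experience, height, weight; 5 IPIP personality traits; PSS-10 stress;
  4 STAQ mood scales (per session); plus BMI, a glasses flag, session start
  hour and session ordinal. The composition of this block is configurable;
  these four extras complete the conventional count of 20 while remaining
  session-constant.

Missing values (no detectable beats, zero SCRs, zero HF power) are NaN in
the feature table and imputed with the session median (global median, then
scale centre) before selection.

### Normalization

Physiological features: subtract the session's baseline value, then min-max
scale within the session to [0, 1]. Kinematics: min-max only (no baseline
exists). Session min/max are computed over the 8 scenario rows, excluding
the baseline row. A zero session range maps the feature to 0.5 and emits a
`DegenerateFeatureWarning`. Characteristics are z-scored across the whole
dataset: they are session-constant, so per-session scaling is undefined,
and a global z-score keeps their scale comparable for selection without
touching session structure.

### Selection, classification, validation

Stepwise forward selection enters, at each step, the candidate with the
smallest partial-F p-value on the nested linear model of the binary label
(ties to the lower column index), while p < 0.05; if the first step admits
nothing the run is retried at 0.1. The reported per-cell feature list and
entry p-values come from selection on the full table (forced to at least
one feature); *accuracies* always come from selection refit inside each
training fold, where an empty selection is allowed and means "no model"
(see tie rule below).

The classifier menu: SVM with linear, inhomogeneous-quadratic and
medium-Gaussian (kernel scale √p, i.e. γ = 1/p) kernels at C = 1;
unregularized logistic regression with the 0.5-output decision rule
(an output of exactly 0.5 goes to the positive class); decision trees with
at most 4/20/100 split nodes (simple/medium/complex); and a boosted
ensemble of 30 depth-3 trees with adaptive reweighting. Validation is
leave-one-sample-out by default (leave-one-participant-out available via
`cv="loso"`). Accuracy per cell is the best classifier's mean fold
accuracy.

Two deliberate reproductions rather than "fixes": (i) sample-wise
leave-one-out lets session-constant characteristics identify sessions, so
the drowsy × characteristics cell is near-ceiling — exactly the behaviour
such a pipeline shows on real data; `cv="loso"` removes it. (ii) The
optimistic variant that selects features once on the full data is available
as `selection="outside"`.

Two calibration choices that matter on effect-free data:

* **Class-balanced training weights.** The factorial design is exactly
  balanced, so each leave-one-out training fold is imbalanced by precisely
  the held-out sample's class. An intercept-dominated classifier then
  predicts the training majority — always the *wrong* class — and
  effect-free accuracy collapses far below chance. All classifiers are
  therefore trained with class-balanced sample weights, which restores the
  design prior; with real effects the weights are ≈ 1 and change nothing.
* **Empty fold selections are allowed.** Forcing a best single feature per
  fold makes near-tied noise candidates flip with the held-out sample, and
  the flip systematically lands on the feature the held-out point
  contradicts, again dragging effect-free accuracy below chance. A fold
  with no admitted feature predicts the positive class (the tie rule at a
  balanced prior).

### Workload validation

For each cause × NASA-TLX outcome, scores are averaged per participant
within each factor level and the paired difference tested; for a two-level
within-subject factor the repeated-measures main-effect F(1, n−1) equals
the squared paired t, which is how it is computed (identity verified to
1e-9 against an independent RM-ANOVA implementation in the tests).
Participants missing a level are excluded with a warning; interactions and
sphericity corrections are out of scope (two-level factors need neither).
Sessions within a sleep condition are averaged per participant before the
drowsy contrast.

## The synthetic study generator

The generator's purpose is testability: every feature an extractor computes
is driven by a named generator parameter, so extractors are validated by
parameter recovery. The models are deliberately minimal:

* **ECG** — Gaussian pulses (σ = 8 ms, 1 mV) at inter-beat intervals
  `60/HR + lf·sin(2π·0.10·t) + hf·sin(2π·0.25·t) + jitter`; motion
  artifacts as broadband half-second bursts (phone scenarios raise their
  amplitude — the gesture-artifact channel). No PQRST morphology.
* **Respiration** — near-sinusoid with slowly drifting instantaneous rate.
* **Skin conductance** — linear tonic drift plus bi-exponential SCRs
  (rise ≈ 1 s, decay ≈ 4 s, unit-peak kernel so amplitudes are in µS);
  SCR events Poisson at 3/min in neutral scenarios.
* **Skin temperature** — slow mean-reverting drift around 33 °C.
* **Kinematics** — mean-reverting (AR(1)) noise for throttle, lateral
  position, offsets and velocities; lane number as a 0/1 semi-Markov
  telegraph process whose occupancy is solved from a target std that
  scales linearly with the dense-traffic multiplier (default 4, so the
  lane-number std ratio between dense and light traffic is ≈ 4 by
  construction); tire slip as clipped near-zero noise whose mean and
  variance rise in snow, scaled by how far road friction drops (default
  60% of the clear-weather value).
* **Questionnaires** — Gaussian scores truncated to each instrument's
  range; drowsy sessions shift the mood scales and start in the early
  morning; each active cause adds its configured shift to the NASA-TLX
  subscales (phone shifts all six — the pattern the workload validation
  should detect).

Condition effects are declared in `EffectConfig.effects[cause]` as additive
(`*_add`) or multiplicative (`*_mult`) shifts on named generator
parameters; `EffectConfig.null()` zeroes them all, leaving only
participant-level offsets and scenario-to-scenario physiological wander
(slow drifts no condition explains). Magnitudes are package choices tuned
to be *moderate* — detectable but not separable at ceiling — because the
reference report gives directions, not magnitudes, for most effects.

What the generator does **not** emulate: realistic waveform morphology,
heavy-tailed artifacts, missing electrodes, learning/boredom trends across
sessions, or correlations between questionnaire traits and physiology.
Passing tests therefore establish that the *procedure* is correct and
calibrated, not that its accuracies transfer to human recordings.

## Numerical choices

* Filters: 4th-order Butterworth, zero-phase (forward–backward); the
  "0–30 Hz band" is a 30 Hz low-pass; the notch is a second-order IIR at
  60 Hz, Q = 30. Filtering happens per continuous session recording before
  epoching. The first/last second of an epoch is excluded from ECG-gradient
  features only.
* R-peak detection: derivative–square–moving-average (150 ms) envelope;
  adaptive threshold at 0.30 × the median of the top 40% of candidate peak
  heights (robust to motion bursts); 250 ms refractory; beat time refined
  to the local |ECG| maximum.
* IBI spectrum: cubic-spline interpolation of the tachogram to 4 Hz,
  detrend, Hann window, periodogram, trapezoid band integration.
* Tonic/phasic split: tonic is a 0.05 Hz zero-phase low-pass computed on a
  block-averaged ~8 Hz grid (the corner is numerically degenerate at
  512 Hz), with the affine trend removed and restored so pure drift passes
  exactly, using a **Bessel** design — Butterworth ringing at the 0.05 Hz
  corner creates spurious response-like bumps after each SCR. Phasic is
  the residual, so tonic + phasic reconstructs the input exactly.
* SCR scoring: peaks of the lightly smoothed (0.3 s) phasic with prominence
  ≥ half the 0.05 µS threshold; amplitude is trough-to-peak within a 5 s
  window, and a net-gain-within-5-s gate realises the rise-time rule
  (slow residual ripple never climbs that fast). Note that a 0.05 Hz
  decomposition necessarily shares ~40% of a slow pulse's *absolute* level
  with the tonic; trough-to-peak amplitude, the quantity scored, is
  preserved (≈ 95% in the tests).
* Respiration rate std uses non-overlapping 1-minute windows (an epoch
  otherwise has a single global rate); breath peaks come from a 1 Hz
  low-passed copy with a minimum spacing of 1.5 s.
* Stepwise selection runs on incrementally orthogonalized residuals, which
  is algebraically identical to refitting nested OLS models (verified
  against an exhaustive statsmodels oracle) but linear-time per step.

## Problem sizes used in tests and the acceptance script

Simulation-heavy checks run the full factorial at reduced sampling rates
(physiology 128 Hz, kinematics 20 Hz) — the statistical claims under test
(counts, chance bounds, rankings) do not depend on the waveform rate — and
classification-matrix checks use 4–8 participants with a reduced classifier
menu. Effect-free calibration is averaged over three replicate studies
because leave-one-out fold outcomes are coupled through the shared
fold-internal selection, making single-run cell accuracies noisier than the
independent-fold binomial rate; for the drowsy cause the label is constant
within sessions, so its chance band uses the 84 independent session units
rather than the 672 rows.

## Known limitations

* Synthetic effect magnitudes are package defaults, not measured values;
  absolute accuracies on synthetic data are not comparable to accuracies on
  human data.
* The R-peak detector assumes upright, high-SNR QRS pulses (true of the
  generator; real ECG needs a hardened detector).
* `rr_std` is ill-defined for epochs shorter than two windows and falls
  back to half-epoch windows.
* The augmented scheme appends *true* indicator bits; a deployed two-stage
  system would append noisy estimates.
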