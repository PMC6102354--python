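# hdscause

Identifying the **cause** of a hazardous driver state — drowsiness, cell-phone
distraction, dense traffic, poor weather — from driver characteristics,
vehicle kinematics and physiological signals.

Detecting *that* a driver is impaired is well studied; knowing *why* matters
just as much, because an intelligent vehicle should react differently to a
texting driver than to a sleep-deprived one. This package re-implements, as a
tested and reusable Python pipeline, a cause-identification analysis built
around a within-subject factorial driving study: every participant drives
multiple sessions (some mildly sleep-deprived), and each session contains one
rest baseline plus eight 4-minute scenarios enumerating every combination of
traffic density × weather × cell-phone use.

Because the original study's human recordings are not redistributable as raw
signals, the package ships a **synthetic study generator** that emulates the
full design — ECG, respiration, skin conductance and skin temperature at the
physiological sampling rate, eight vehicle-kinematics channels, and
questionnaire scores (IPIP, PSS-10, STAQ, NASA-TLX) — with configurable,
parameter-transparent condition effects. Every downstream stage is therefore
testable end-to-end by parameter recovery, with no downloads.

## The pipeline

1. **Simulate** (or load) a study: `StudyDesign` (21 × 4 × 8 factorial by
   default) + `EffectConfig` → raw multichannel recordings + questionnaires.
2. **Preprocess**: respiration/skin conductance/skin temperature through a
   0–30 Hz band (30 Hz low-pass); ECG through a 5 Hz high-pass plus 60 Hz
   notch; all zero-phase. Slice each session into baseline + scenario epochs.
3. **Extract 61 features per scenario**: 17 physiological (breathing rate
   statistics and RMSSD of breath periods; mean and first-vs-last-second
   change of skin temperature and tonic skin conductance; skin-conductance
   response count/amplitude statistics; mean HR, IBI std, ECG gradient
   statistics, and LF (0.04–0.15 Hz) / HF (0.15–0.4 Hz) band powers of the
   inter-beat-interval spectrum with their ratio), 24 kinematics
   (mean/std/fluctuation of 8 channels), 20 driver characteristics.
4. **Normalize per session**: physiological features are baseline-subtracted
   then min-max scaled within the session,
   `x'' = (x − baseline − min) / (max − min)`; kinematics the same without
   the baseline step; characteristics z-scored across the dataset.
5. **Classify each cause** (present/absent) from any of the 7 feature-set
   combinations: stepwise forward selection by partial F-test (entry
   p < 0.05, escalated to 0.1 if nothing enters), refit **inside every
   leave-one-out training fold**, over a menu of SVMs (linear / quadratic /
   medium-Gaussian kernels), logistic regression, decision trees
   (simple/medium/complex) and a boosted-tree ensemble. An *augmented*
   scheme adds the other three causes' true presence bits as candidates.
6. **Validate workload**: within-subject main-effect tests of each cause on
   the six NASA-TLX subscales and the overall score (for a two-level within
   factor the RM-ANOVA F is exactly the squared paired t).

## Worked example

```python
import warnings
import hdscause as h
from hdscause.classification import ClassifierSpec, run_matrix, accuracy_table

design = h.StudyDesign(n_participants=4, physio_rate=128.0,
                       kinematics_rate=20.0, seed=2)
study = h.simulate_study(design)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    table = h.normalize_features(h.extract_features(study))
    menu = [ClassifierSpec("logistic"), ClassifierSpec("svm", kernel="linear"),
            ClassifierSpec("tree", tree_complexity="medium")]
    results = run_matrix(table, menu=menu, seed=2)
print(accuracy_table(results))
```

prints (4 participants, default synthetic effects; this is
`examples/03_classify_causes.py`):

```
                                    Cell phone Alert vs. drowsy Highway vs. town Snowy vs. clear
Physiology                              100.0%            50.0%            85.2%           74.2%
Characteristics                              -           100.0%                -               -
Vehicle kinematics                       72.7%            42.2%           100.0%          100.0%
Physiology, characteristics             100.0%           100.0%            85.2%           74.2%
Physiology, vehicle kinematics          100.0%            42.2%           100.0%          100.0%
Characteristics, vehicle kinematics      72.7%           100.0%           100.0%          100.0%
All                                     100.0%           100.0%           100.0%          100.0%
```

Read it like the study's report: drowsiness is best identified from driver
characteristics (mood is asked once per session, so it tracks the
session-level sleep condition), traffic density and weather from vehicle
kinematics (lane-change rate, tire slip, throttle variance), and phone use
from physiology (respiration rate, ECG motion artifacts). A `-` cell means
the target varies within a session but every selected feature is
session-constant, so the cell is not classifiable. Exact percentages vary
with the seed and the synthetic effect sizes; the ranking is the stable
scientific content.

The same stages are scriptable from a shell:

```bash
hds simulate --config cfg.json --out study/ --seed 1
hds features --in study/ --out features.csv
hds classify --features features.csv --scheme independent --cv loo --out results/
hds tlx --in study/ --out table2.csv
```

See `examples/` for one short narrative script per capability.

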