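"""Classify each cause of a hazardous driver state from feature subsets.

Runs the cause x feature-set experiment matrix: stepwise forward F-test
selection (p < 0.05, escalated to 0.1) refit inside every leave-one-out
training fold, a small classifier menu, and the best classifier per cell.
Prints the accuracy grid and the best features per cause — on default
synthetic effects, drowsiness is read from driver characteristics,
traffic and weather from kinematics, and phone use from physiology.
"""

import warnings

import hdscause as h
from hdscause.classification import ClassifierSpec, report, run_matrix

design = h.StudyDesign(n_participants=4, physio_rate=128.0,
                       kinematics_rate=20.0, seed=2)
study = h.simulate_study(design)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    table = h.normalize_features(h.extract_features(study))
    menu = [ClassifierSpec("logistic"), ClassifierSpec("svm", kernel="linear"),
            ClassifierSpec("tree", tree_complexity="medium")]
    results = run_matrix(table, menu=menu, seed=2)

print(report(results))
print("A '-' cell means the target varies within sessions but every "
      "selected feature is session-constant, so the cell is not "
      "classifiable (questionnaires cannot track scenario-level causes).")
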