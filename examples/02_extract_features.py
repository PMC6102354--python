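"""Extract and normalize the 61-feature table from a synthetic study.

Each scenario row carries 17 physiological features (respiration, skin
temperature, skin conductance, ECG), 24 vehicle-kinematics features
(mean/std/fluctuation of 8 channels) and 20 driver characteristics.
Physiological features are baseline-subtracted and min-max scaled per
session; kinematics are min-max scaled; characteristics are z-scored.
"""

import warnings

import hdscause as h

design = h.StudyDesign(n_participants=3, physio_rate=128.0,
                       kinematics_rate=20.0, seed=1)
study = h.simulate_study(design)
table = h.extract_features(study)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    norm = h.normalize_features(table)

print(f"feature table: {len(norm)} scenario rows x {len(h.ALL_FEATURES)} features")
cols = ["participant", "session", "phone", "hr_mean", "rr_mean",
        "scr_count", "lane_number_std"]
print("\nA few normalized columns (phone scenarios breathe faster, so "
      "rr_mean sits high within each session):")
print(norm[cols].head(8).round(3).to_string(index=False))
print("\nRaw (unnormalized) means by phone label:")
raw_scen = table[table["role"] == "scenario"]
print(raw_scen.groupby("phone")[["rr_mean", "ecg_grad_absmean"]].mean().round(2))
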