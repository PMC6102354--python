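"""Per-session feature normalization.

Physiological features: the session's baseline value is subtracted from
each scenario value, then the session minimum is subtracted and the result
divided by the session range (min-max to [0, 1]).  Vehicle-kinematics
features get the same min-max step without baseline subtraction (there is
no kinematics baseline).  Driver characteristics are session-constant and
instead z-scored across the whole dataset.

A feature whose session range is zero is mapped to 0.5 (the centre of the
scale) and reported through a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .features import (ALL_FEATURES, CHARACTERISTICS_FEATURES,
                       KINEMATICS_FEATURES, PHYSIO_FEATURES)


class DegenerateFeatureWarning(UserWarning):
    """A feature had zero range (or variance) where a spread was expected."""


def _minmax(block: pd.DataFrame, context: str) -> pd.DataFrame:
    lo, hi = block.min(), block.max()
    rng = hi - lo
    out = (block - lo) / rng.replace(0.0, np.nan)
    degenerate = rng.index[(rng == 0.0) & lo.notna()]
    for col in degenerate:
        out[col] = 0.5
        warnings.warn(f"degenerate range for '{col}' in {context}; set to 0.5",
                      DegenerateFeatureWarning, stacklevel=3)
    return out


def normalize_physio(baseline: pd.Series, scenarios: pd.DataFrame,
                     context: str = "session") -> pd.DataFrame:
    """Baseline-subtract then session min-max the physiological block."""
    if len(scenarios) < 2:
        raise ValueError("need at least 2 scenarios per session to normalize")
    shifted = scenarios - baseline
    return _minmax(shifted, context)


def normalize_kinematics(scenarios: pd.DataFrame, context: str = "session"
                         ) -> pd.DataFrame:
    """Session min-max of the kinematics block (no baseline step)."""
    if len(scenarios) < 2:
        raise ValueError("need at least 2 scenarios per session to normalize")
    return _minmax(scenarios, context)


def normalize_features(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize a full feature table (as built by ``extract_features``).

    Returns scenario rows only, with physiological and kinematics features
    in [0, 1] per session and characteristics z-scored across the dataset.
    NaN feature values stay NaN (imputation happens at classification time).
    """
    out_blocks = []
    for (p, s), grp in table.groupby(["participant", "session"], sort=True):
        base = grp[grp["role"] == "baseline"]
        scen = grp[grp["role"] == "scenario"].copy()
        if base.empty:
            raise ValueError(f"no baseline row for participant {p}, session {s}")
        ctx = f"participant {p} session {s}"
        scen.loc[:, list(PHYSIO_FEATURES)] = normalize_physio(
            base.iloc[0][list(PHYSIO_FEATURES)].astype(float),
            scen[list(PHYSIO_FEATURES)].astype(float), ctx).to_numpy()
        scen.loc[:, list(KINEMATICS_FEATURES)] = normalize_kinematics(
            scen[list(KINEMATICS_FEATURES)].astype(float), ctx).to_numpy()
        out_blocks.append(scen)
    out = pd.concat(out_blocks, ignore_index=True)
    chars = out[list(CHARACTERISTICS_FEATURES)].astype(float)
    mu, sd = chars.mean(), chars.std(ddof=0)
    zero_sd = sd.index[sd == 0.0]
    for col in zero_sd:
        warnings.warn(f"degenerate variance for characteristic '{col}'; set to 0",
                      DegenerateFeatureWarning, stacklevel=2)
    z = (chars - mu) / sd.replace(0.0, np.nan)
    z[zero_sd] = 0.0
    out.loc[:, list(CHARACTERISTICS_FEATURES)] = z.to_numpy()
    return out


def impute_session_median(table: pd.DataFrame,
                          columns=ALL_FEATURES) -> pd.DataFrame:
    """Replace NaNs with the session median (global median, then 0.5, as
    fallbacks when a whole session or dataset is missing)."""
    out = table.copy()
    cols = [c for c in columns if c in out.columns]
    med = out.groupby(["participant", "session"])[cols].transform("median")
    out[cols] = out[cols].fillna(med)
    out[cols] = out[cols].fillna(out[cols].median())
    out[cols] = out[cols].fillna(0.5)
    return out
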