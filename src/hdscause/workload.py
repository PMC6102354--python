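"""Within-subject validation of induced workload.

For each of the four causes and each NASA-TLX outcome (six subscales plus
the overall score), a repeated-measures main-effect test: average the
outcome within each factor level per participant, then test the paired
difference.  For a two-level within-subject factor the RM-ANOVA
main-effect F with (1, n-1) degrees of freedom is exactly the squared
paired t statistic, which is how it is computed here.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .design import CAUSES
from .simulate import TLX_SUBSCALES

TLX_OUTCOMES = TLX_SUBSCALES + ("overall",)


def rm_main_effect(tlx: pd.DataFrame, factor: str, outcome: str
                   ) -> tuple[float, float]:
    """Main-effect (F, p) of a two-level within-subject factor on a TLX outcome.

    Participants missing either factor level are excluded with a warning;
    fewer than 3 complete participants is an error.
    """
    from scipy import stats

    if factor not in tlx.columns:
        raise KeyError(f"factor {factor!r} not in table")
    if outcome not in tlx.columns:
        raise KeyError(f"outcome {outcome!r} not in table")
    diffs = []
    for p, grp in tlx.groupby("participant"):
        means = grp.groupby(factor)[outcome].mean()
        if set(means.index) != {0, 1}:
            warnings.warn(f"participant {p} lacks both levels of {factor!r}; excluded",
                          stacklevel=2)
            continue
        diffs.append(means[1] - means[0])
    if len(diffs) < 3:
        raise ValueError(f"fewer than 3 complete participants for factor {factor!r}")
    d = np.asarray(diffs, dtype=float)
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        return (0.0, 1.0) if d.mean() == 0.0 else (float("inf"), 0.0)
    t = d.mean() / (sd / np.sqrt(n))
    F = t * t
    p = float(stats.f.sf(F, 1, n - 1))
    return float(F), p


def tlx_significance_table(tlx: pd.DataFrame, factors=CAUSES,
                           outcomes=TLX_OUTCOMES) -> pd.DataFrame:
    """Grid of main-effect p-values: one row per TLX outcome, one column per
    cause (the study's workload-validation table layout)."""
    out = {}
    for factor in factors:
        out[factor] = {o: rm_main_effect(tlx, factor, o)[1] for o in outcomes}
    return pd.DataFrame(out).reindex(list(outcomes))
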