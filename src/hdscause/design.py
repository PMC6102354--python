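"""Factorial study design: participants x sessions x scenarios.

The design mirrors a multi-session driving-simulator protocol: each
participant completes ``n_sessions_per_participant`` sessions (exactly two
flagged drowsy, i.e. mildly sleep-deprived), and each session consists of one
rest baseline followed by ``scenarios_per_session`` driving scenarios that
enumerate every combination of traffic density (town/highway), weather
(snowy/clear) and cell-phone use, in seeded random order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import product

import numpy as np
import pandas as pd

#: The four binary causes of a hazardous driver state.
CAUSES = ("phone", "drowsy", "town", "snowy")

#: Causes that vary scenario-to-scenario within a session (drowsy does not).
WITHIN_SESSION_CAUSES = ("phone", "town", "snowy")


@dataclass(frozen=True)
class ConditionLabels:
    """Presence/absence of each cause for one scenario.

    ``drowsy`` is a session-level property (sleep deprivation spans the whole
    session); the other three flip scenario to scenario.
    """

    phone: int
    drowsy: int
    town: int
    snowy: int

    def as_dict(self) -> dict[str, int]:
        return {c: int(getattr(self, c)) for c in CAUSES}


@dataclass
class StudyDesign:
    """Layout parameters of the factorial study.

    Defaults reproduce the reference protocol: 21 participants, 4 sessions
    each (2 drowsy / 2 alert), 8 scenarios of 4 min per session plus a 4-min
    baseline, physiology sampled at 512 Hz and vehicle kinematics at 60 Hz.
    """

    n_participants: int = 21
    n_sessions_per_participant: int = 4
    n_drowsy_sessions: int = 2
    scenarios_per_session: int = 8
    scenario_duration: float = 240.0
    baseline_duration: float = 240.0
    physio_rate: float = 512.0
    kinematics_rate: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "n_participants",
            "n_sessions_per_participant",
            "scenarios_per_session",
            "scenario_duration",
            "baseline_duration",
            "physio_rate",
            "kinematics_rate",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if not 0 <= self.n_drowsy_sessions <= self.n_sessions_per_participant:
            raise ValueError(
                "n_drowsy_sessions must lie in "
                f"[0, {self.n_sessions_per_participant}], got {self.n_drowsy_sessions}"
            )

    # -- derived sizes -----------------------------------------------------
    @property
    def n_sessions(self) -> int:
        return self.n_participants * self.n_sessions_per_participant

    @property
    def n_scenarios(self) -> int:
        return self.n_sessions * self.scenarios_per_session

    @property
    def session_duration(self) -> float:
        return self.baseline_duration + self.scenarios_per_session * self.scenario_duration

    def as_dict(self) -> dict:
        return asdict(self)

    # -- layout ------------------------------------------------------------
    def layout(self) -> pd.DataFrame:
        """Segment table for the whole study.

        One row per segment (baseline or scenario) with columns
        ``participant, session, segment, role, start_s, end_s`` plus the four
        binary cause labels (labels are 0 on baseline rows except ``drowsy``,
        which is a property of the session).

        Within each session the scenarios enumerate all 2x2x2 combinations of
        (town, snowy, phone) exactly once when ``scenarios_per_session`` is 8
        (the default); other counts draw combinations cyclically from a
        shuffled enumeration.
        """
        rng = np.random.default_rng(self.seed)
        triples = list(product((0, 1), repeat=3))  # (town, snowy, phone)
        rows = []
        for p in range(1, self.n_participants + 1):
            drowsy_flags = np.zeros(self.n_sessions_per_participant, dtype=int)
            drowsy_flags[: self.n_drowsy_sessions] = 1
            rng.shuffle(drowsy_flags)
            for s in range(1, self.n_sessions_per_participant + 1):
                drowsy = int(drowsy_flags[s - 1])
                order = [triples[i % len(triples)] for i in range(self.scenarios_per_session)]
                rng.shuffle(order)
                t = 0.0
                rows.append(
                    dict(
                        participant=p, session=s, segment=0, role="baseline",
                        start_s=t, end_s=t + self.baseline_duration,
                        phone=0, drowsy=drowsy, town=0, snowy=0,
                    )
                )
                t += self.baseline_duration
                for k, (town, snowy, phone) in enumerate(order, start=1):
                    rows.append(
                        dict(
                            participant=p, session=s, segment=k, role="scenario",
                            start_s=t, end_s=t + self.scenario_duration,
                            phone=phone, drowsy=drowsy, town=town, snowy=snowy,
                        )
                    )
                    t += self.scenario_duration
        return pd.DataFrame(rows)


def labels_from_row(row) -> ConditionLabels:
    """Build :class:`ConditionLabels` from a layout/segments table row."""
    return ConditionLabels(
        phone=int(row["phone"]), drowsy=int(row["drowsy"]),
        town=int(row["town"]), snowy=int(row["snowy"]),
    )


# ---------------------------------------------------------------------------
# Condition effects
# ---------------------------------------------------------------------------

def _default_effects() -> dict[str, dict[str, float]]:
    # Additive entries end in "_add" (units of the target parameter),
    # multiplicative ones in "_mult".  Directions follow the study's
    # reported best features per cause; magnitudes are generator choices.
    return {
        "phone": {
            "resp_rate_add": 2.5,          # breaths/min
            "artifact_power_add": 0.5,     # ECG broadband burst amplitude
            "lat_pos_mean_add": 0.08,      # m, drift off lane centre
            "tlx_mental_add": 20.0, "tlx_physical_add": 20.0,
            "tlx_temporal_add": 20.0, "tlx_performance_add": 20.0,
            "tlx_effort_add": 20.0, "tlx_frustration_add": 20.0,
        },
        "drowsy": {
            "staq_negative_add": 12.0,
            "staq_positive_add": -12.0,
            "staq_activated_add": -8.0,
            "staq_inactivated_add": 8.0,
            "tonic_slope_add": 0.00125,    # uS/s (~0.3 uS over 4 min)
            "start_hour_add": -8.0,        # drowsy sessions run in the early morning
            "tlx_frustration_add": 5.0, "tlx_performance_add": 5.0,
        },
        "town": {
            "lane_std_mult": 4.0,          # lane-number std multiplier
            "lf_amp_add": 0.010,           # s, 0.1 Hz IBI modulation depth
            "scr_amp_std_mult": 2.5,
            "tlx_temporal_add": 5.0,
        },
        "snowy": {
            "slip_mean_add": 0.08,         # slip fraction, rear tires
            "slip_std_mult": 4.0,
            "throttle_std_mult": 1.8,
            "tonic_mean_add": 0.25,        # uS
            "tlx_mental_add": 9.0, "tlx_physical_add": 4.0,
            "tlx_temporal_add": 4.0, "tlx_performance_add": 4.0,
            "tlx_effort_add": 4.0,
        },
    }


@dataclass
class EffectConfig:
    """Condition-dependent effect sizes and neutral signal parameters.

    ``effects[cause]`` maps a generator parameter to an additive shift
    (``*_add``, in the parameter's units) or a multiplicative factor
    (``*_mult``) applied when that cause is present in a scenario.
    The remaining fields are the neutral-scenario generator settings.
    """

    effects: dict[str, dict[str, float]] = field(default_factory=_default_effects)
    noise: dict[str, float] = field(
        default_factory=lambda: {
            "ecg": 0.01, "resp": 0.05, "gsr": 0.01, "st": 0.005,
            "kinematics": 1.0, "ibi": 0.01,
        }
    )
    # scenario-to-scenario physiological wander (sd of a per-segment offset):
    # slow drifts over a 45-min session that no condition explains
    scenario_wander: dict[str, float] = field(
        default_factory=lambda: {
            "mean_hr": 1.5, "resp_rate": 0.8, "tonic_mean": 0.30,
            "lat_pos_mean": 0.05, "st_mean": 0.15,
        }
    )
    scr_rate: float = 3.0          # events/min in neutral scenarios
    mayer_freq: float = 0.10       # Hz, low-frequency IBI modulation
    resp_freq: float = 0.25        # Hz, neutral breathing (15 breaths/min)
    snow_friction_factor: float = 0.60

    def __post_init__(self) -> None:
        for name in ("scr_rate", "mayer_freq", "resp_freq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.snow_friction_factor <= 1:
            raise ValueError("snow_friction_factor must lie in (0, 1]")

    @classmethod
    def null(cls) -> "EffectConfig":
        """All condition effects switched off (labels carry no signal)."""
        cfg = cls()
        cfg.effects = {
            cause: {k: (1.0 if k.endswith("_mult") else 0.0) for k in d}
            for cause, d in cfg.effects.items()
        }
        return cfg

    def shifted(self, labels: ConditionLabels, param: str, base: float) -> float:
        """Apply every active cause's shift for ``param`` to ``base``."""
        value = float(base)
        for cause in CAUSES:
            if not getattr(labels, cause):
                continue
            d = self.effects.get(cause, {})
            if f"{param}_add" in d:
                value += d[f"{param}_add"]
            if f"{param}_mult" in d:
                value *= d[f"{param}_mult"]
        return value

    def as_dict(self) -> dict:
        return asdict(self)
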