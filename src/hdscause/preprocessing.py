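"""Channel filtering and epoching.

Respiration, skin conductance and skin temperature go through a 0-30 Hz
band (realised as a 30 Hz low-pass, since the band starts at DC); ECG goes
through a 5 Hz high-pass plus a 60 Hz notch for mains interference.  All
filters are 4th-order Butterworth (the notch a second-order IIR, Q = 30)
applied forward-backward so event timings are not shifted.

Epoching slices a continuous session recording into its baseline and
scenario segments after filtering, so filter transients do not line up
with segment boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .design import ConditionLabels, labels_from_row
from .simulate import KIN_CHANNELS, SessionRecording

LOWPASS_HZ = 30.0
ECG_HIGHPASS_HZ = 5.0
NOTCH_HZ = 60.0
NOTCH_Q = 30.0


def filter_lowband(x, rate: float) -> np.ndarray:
    """0-30 Hz band (zero-phase 30 Hz low-pass) for resp/GSR/ST channels."""
    if rate <= 2 * LOWPASS_HZ:
        raise ValueError(
            f"sampling rate {rate} Hz too low for a {LOWPASS_HZ} Hz band")
    sos = signal.butter(4, LOWPASS_HZ, btype="low", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def filter_ecg(x, rate: float) -> np.ndarray:
    """5 Hz high-pass plus 60 Hz notch (both zero-phase) for ECG."""
    if rate <= 2 * NOTCH_HZ:
        raise ValueError(f"sampling rate {rate} Hz too low for a {NOTCH_HZ} Hz notch")
    x = np.asarray(x, dtype=float)
    sos = signal.butter(4, ECG_HIGHPASS_HZ, btype="high", fs=rate, output="sos")
    y = signal.sosfiltfilt(sos, x)
    b, a = signal.iirnotch(NOTCH_HZ, NOTCH_Q, fs=rate)
    return signal.filtfilt(b, a, y)


def filter_physio(physio: pd.DataFrame, rate: float) -> pd.DataFrame:
    """Apply the per-channel filters to a 4-channel physiology frame."""
    out = pd.DataFrame(index=physio.index)
    out["ecg"] = filter_ecg(physio["ecg"].to_numpy(), rate)
    for ch in ("resp", "gsr", "st"):
        out[ch] = filter_lowband(physio[ch].to_numpy(), rate)
    return out


@dataclass
class Epoch:
    """One baseline or scenario segment, filtered and time-sliced."""

    participant: int
    session: int
    segment: int
    role: str
    labels: ConditionLabels | None
    physio: pd.DataFrame
    physio_rate: float
    kinematics: pd.DataFrame | None
    kinematics_rate: float


def epoch(recording: SessionRecording, segments: pd.DataFrame | None = None,
          prefiltered: bool = False) -> list[Epoch]:
    """Filter a session recording and slice it into per-segment epochs.

    ``segments`` defaults to the recording's own segment table.  Rows must
    lie within the recording span and not overlap; offending rows are
    reported together in the error message.
    """
    seg = (segments if segments is not None else recording.segments).copy()
    if seg.empty:
        return []
    seg = seg.sort_values("start_s").reset_index(drop=True)
    span = len(recording.physio) / recording.physio_rate
    bad = []
    for i, row in seg.iterrows():
        if row["start_s"] < 0 or row["end_s"] > span + 1e-9 or row["end_s"] <= row["start_s"]:
            bad.append(f"row {i}: [{row['start_s']}, {row['end_s']}] outside [0, {span:.3f}]")
        if i > 0 and row["start_s"] < seg.loc[i - 1, "end_s"] - 1e-9:
            bad.append(f"row {i}: overlaps row {i - 1}")
    if bad:
        raise ValueError("invalid segment table: " + "; ".join(bad))

    physio = recording.physio if prefiltered else filter_physio(
        recording.physio, recording.physio_rate)
    kin = recording.kinematics
    out = []
    for _, row in seg.iterrows():
        i0 = int(round(row["start_s"] * recording.physio_rate))
        i1 = int(round(row["end_s"] * recording.physio_rate))
        k0 = int(round(row["start_s"] * recording.kinematics_rate))
        k1 = int(round(row["end_s"] * recording.kinematics_rate))
        role = str(row["role"])
        out.append(Epoch(
            participant=int(row["participant"]), session=int(row["session"]),
            segment=int(row["segment"]), role=role,
            labels=labels_from_row(row) if role == "scenario" else None,
            physio=physio.iloc[i0:i1].reset_index(drop=True),
            physio_rate=recording.physio_rate,
            kinematics=(kin.iloc[k0:k1].reset_index(drop=True)
                        if kin is not None and len(kin) else None),
            kinematics_rate=recording.kinematics_rate,
        ))
    return out
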