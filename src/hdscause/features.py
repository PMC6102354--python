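"""Per-epoch feature extraction.

Seventeen physiological features (respiration, skin temperature, skin
conductance, ECG), twenty-four vehicle-kinematics features (mean, standard
deviation and "fluctuation" — mean absolute first difference — of each of
the eight channels) and twenty driver-characteristics features per
scenario row, for a 61-column feature matrix.

Features that cannot be computed (fewer than two heartbeats, zero skin
conductance responses, zero high-frequency power) are returned as NaN and
imputed later, before feature selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline

from .design import CAUSES
from .preprocessing import Epoch, epoch as _epoch
from .simulate import IPIP_TRAITS, KIN_CHANNELS, STAQ_SCALES

LF_BAND = (0.04, 0.15)   # Hz
HF_BAND = (0.15, 0.40)   # Hz
IBI_RESAMPLE_HZ = 4.0
SCR_MIN_AMP = 0.05       # uS
SCR_MAX_RISE = 5.0       # s
R_REFRACTORY = 0.250     # s

PHYSIO_FEATURES = (
    "rr_mean", "rr_std", "rr_rmssd",
    "st_mean", "st_delta",
    "gsr_tonic_mean", "gsr_tonic_delta",
    "scr_count", "scr_amp_mean", "scr_amp_std",
    "hr_mean", "ibi_std", "ecg_grad_median", "ecg_grad_absmean",
    "lf_power", "hf_power", "lf_hf_ratio",
)
KINEMATICS_FEATURES = tuple(
    f"{ch}_{stat}" for ch in KIN_CHANNELS for stat in ("mean", "std", "fluct"))
CHARACTERISTICS_FEATURES = (
    "age", "gender", "dominant_hand", "driving_experience", "height", "weight",
    *(f"ipip_{t}" for t in IPIP_TRAITS),
    "pss10",
    *(f"staq_{s}" for s in STAQ_SCALES),
    "bmi", "glasses", "session_start_hour", "session_ordinal",
)
FEATURE_SETS = {
    "physio": PHYSIO_FEATURES,
    "kinematics": KINEMATICS_FEATURES,
    "characteristics": CHARACTERISTICS_FEATURES,
}
ALL_FEATURES = PHYSIO_FEATURES + KINEMATICS_FEATURES + CHARACTERISTICS_FEATURES
ID_COLUMNS = ("participant", "session", "segment", "role")

assert len(PHYSIO_FEATURES) == 17 and len(KINEMATICS_FEATURES) == 24
assert len(CHARACTERISTICS_FEATURES) == 20 and len(ALL_FEATURES) == 61


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg_filtered, rate: float) -> np.ndarray:
    """R-wave times via a derivative-square-moving-average energy detector.

    The squared first derivative is smoothed over a 150 ms window; peaks of
    the envelope above an adaptive threshold (a fraction of the upper
    envelope percentile) are kept with a 250 ms refractory period, then each
    beat time is refined to the local absolute ECG maximum.
    """
    x = np.asarray(ecg_filtered, dtype=float)
    if x.size < rate:
        return np.array([])
    d = np.diff(x)
    env = signal.fftconvolve(d * d, np.ones(int(0.150 * rate)) / (0.150 * rate),
                             mode="same")
    cand, _ = signal.find_peaks(env, distance=int(R_REFRACTORY * rate))
    if cand.size == 0:
        return np.array([])
    # adaptive threshold from the upper bulk of candidate-peak heights: the
    # median of the top 40% tracks the QRS envelope level and is insensitive
    # to a few high-energy motion bursts and to the noise-floor majority
    heights = np.sort(env[cand])[::-1]
    top = heights[: max(1, int(0.4 * heights.size))]
    thr = 0.30 * np.median(top)
    if thr <= 0:
        return np.array([])
    peaks = cand[env[cand] >= thr]
    half = int(0.040 * rate)
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(x.size, p + half)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    beats = np.unique(refined) / rate
    if beats.size > 1:  # refinement may merge neighbours; re-enforce refractory
        keep = np.concatenate([[True], np.diff(beats) >= R_REFRACTORY])
        beats = beats[keep]
    return beats


def _ibi_band_powers(beats: np.ndarray) -> tuple[float, float]:
    """LF/HF band powers of the inter-beat-interval series.

    The IBI tachogram is cubic-interpolated onto a 4 Hz grid, detrended,
    Hann-windowed, and the periodogram integrated over each band by the
    trapezoid rule.
    """
    ibi = np.diff(beats)
    t = beats[1:]
    if ibi.size < 8 or (t[-1] - t[0]) < 2.0 / LF_BAND[0] / 2:
        return np.nan, np.nan
    grid = np.arange(t[0], t[-1], 1.0 / IBI_RESAMPLE_HZ)
    x = CubicSpline(t, ibi)(grid)
    x = signal.detrend(x)
    f, pxx = signal.periodogram(x, fs=IBI_RESAMPLE_HZ, window="hann")
    lf = float(np.trapezoid(pxx[(f >= LF_BAND[0]) & (f < LF_BAND[1])],
                            f[(f >= LF_BAND[0]) & (f < LF_BAND[1])]))
    hf = float(np.trapezoid(pxx[(f >= HF_BAND[0]) & (f < HF_BAND[1])],
                            f[(f >= HF_BAND[0]) & (f < HF_BAND[1])]))
    return lf, hf


def ecg_features(ecg_filtered, beats, rate: float) -> dict[str, float]:
    """Seven ECG features: mean HR, IBI std, two gradient statistics, and
    LF/HF spectral powers with their ratio.

    Gradient features come from the first difference of the filtered ECG
    with the first and last second excluded (filter edge transients).
    """
    x = np.asarray(ecg_filtered, dtype=float)
    trim = int(rate)
    core = x[trim:-trim] if x.size > 2 * trim else x
    grad = np.diff(core) * rate  # per-second units, rate-invariant
    out = dict.fromkeys(
        ("hr_mean", "ibi_std", "lf_power", "hf_power", "lf_hf_ratio"), np.nan)
    out["ecg_grad_median"] = float(np.median(grad)) if grad.size else np.nan
    out["ecg_grad_absmean"] = float(np.mean(np.abs(grad))) if grad.size else np.nan
    beats = np.asarray(beats, dtype=float)
    if beats.size < 2:
        return out
    ibi = np.diff(beats)
    out["hr_mean"] = 60.0 / float(np.mean(ibi))
    out["ibi_std"] = float(np.std(ibi, ddof=1)) if ibi.size > 1 else 0.0
    lf, hf = _ibi_band_powers(beats)
    out["lf_power"], out["hf_power"] = lf, hf
    out["lf_hf_ratio"] = lf / hf if hf and hf > 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# Respiration
# ---------------------------------------------------------------------------

def _breath_peaks(resp_filtered, rate: float) -> np.ndarray:
    x = np.asarray(resp_filtered, dtype=float)
    sos = signal.butter(2, 1.0, btype="low", fs=rate, output="sos")
    sm = signal.sosfiltfilt(sos, x)
    prom = 0.3 * np.std(sm)
    peaks, _ = signal.find_peaks(sm, distance=int(1.5 * rate), prominence=prom)
    return peaks / rate


def respiration_features(resp_filtered, rate: float) -> dict[str, float]:
    """Mean respiration rate (breaths/min), its std over 1-min windows, and
    the RMS of successive breath-period differences (s)."""
    peaks = _breath_peaks(resp_filtered, rate)
    out = dict(rr_mean=np.nan, rr_std=np.nan, rr_rmssd=np.nan)
    if peaks.size < 3:
        return out
    periods = np.diff(peaks)
    out["rr_mean"] = 60.0 / float(np.mean(periods))
    duration = len(np.asarray(resp_filtered)) / rate
    win = 60.0 if duration >= 120.0 else duration / 2.0
    rates = []
    for w0 in np.arange(0.0, duration - win + 1e-9, win):
        sel = periods[(peaks[1:] > w0) & (peaks[1:] <= w0 + win)]
        if sel.size:
            rates.append(60.0 / np.mean(sel))
    if len(rates) > 1:
        out["rr_std"] = float(np.std(rates, ddof=1))
    succ = np.diff(periods)
    if succ.size:
        out["rr_rmssd"] = float(np.sqrt(np.mean(succ ** 2)))
    return out


# ---------------------------------------------------------------------------
# Skin temperature and skin conductance
# ---------------------------------------------------------------------------

def st_features(st_filtered, rate: float) -> dict[str, float]:
    """Mean skin temperature and last-second minus first-second difference."""
    x = np.asarray(st_filtered, dtype=float)
    if x.size < 2 * rate:
        raise ValueError("skin-temperature epoch must span at least 2 s")
    n1 = int(rate)
    return dict(st_mean=float(np.mean(x)),
                st_delta=float(np.mean(x[-n1:]) - np.mean(x[:n1])))


def gsr_decompose(gsr_filtered, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Split skin conductance into tonic (0.05 Hz low-pass, zero-phase) and
    phasic (residual) components; tonic + phasic reconstructs the input
    exactly by construction.

    The tonic estimate is computed on a block-averaged ~8 Hz grid (a 0.05 Hz
    corner at a 512 Hz rate is numerically degenerate) with a 4th-order
    zero-phase Butterworth, then interpolated back to the original grid.
    """
    x = np.asarray(gsr_filtered, dtype=float)
    q = max(1, int(round(rate / 8.0)))
    n_blocks = x.size // q
    if n_blocks < 16:
        sos = signal.bessel(4, min(0.05, 0.45 * rate), btype="low", fs=rate,
                            output="sos", norm="mag")
        tonic = signal.sosfiltfilt(sos, x)
        return tonic, x - tonic
    xs = x[: n_blocks * q].reshape(n_blocks, q).mean(axis=1)
    fs = rate / q
    # remove the affine trend before filtering (and restore it after) so a
    # pure drift passes into the tonic exactly, free of edge transients
    k = np.arange(n_blocks)
    coef = np.polyfit(k, xs, 1)
    trend = np.polyval(coef, k)
    # Bessel rather than Butterworth: its step response barely overshoots,
    # so the tonic does not ring after each phasic pulse (Butterworth
    # ringing at 1/0.05 Hz produces spurious response-like bumps)
    sos = signal.bessel(4, 0.05, btype="low", fs=fs, output="sos", norm="mag")
    ts = signal.sosfiltfilt(sos, xs - trend) + trend
    centers = (np.arange(n_blocks) + 0.5) * q
    tonic = np.interp(np.arange(x.size), centers, ts)
    return tonic, x - tonic


def scr_score(phasic, rate: float, min_amp: float = SCR_MIN_AMP
              ) -> tuple[int, float, float]:
    """Count and amplitude statistics of skin conductance responses.

    A response is a trough-to-peak excursion of the phasic component with
    amplitude >= ``min_amp`` (uS) and rise time <= 5 s.
    """
    if min_amp <= 0:
        raise ValueError("min_amp must be positive")
    x = np.asarray(phasic, dtype=float)
    w = max(1, int(0.3 * rate))  # light smoothing: SCR dynamics are ~1 s+
    x = signal.fftconvolve(x, np.ones(w) / w, mode="same")
    peaks, _ = signal.find_peaks(x, distance=max(1, int(1.0 * rate)),
                                 prominence=0.5 * min_amp)
    back = max(1, int(SCR_MAX_RISE * rate))
    amps = []
    for p in peaks:
        lo = max(0, p - back)
        seg = x[lo:p + 1]
        amp = float(x[p] - seg.min())
        # the rise-time constraint realised as a net-gain gate: a genuine
        # response climbs by at least the threshold within the 5 s window,
        # while slow tonic-residual ripple (period tens of seconds) does not
        fast_gain = float(x[p] - seg[0])
        if amp >= min_amp and fast_gain >= min_amp:
            amps.append(amp)
    if not amps:
        return 0, np.nan, np.nan
    a = np.asarray(amps)
    return int(a.size), float(a.mean()), float(a.std(ddof=0))


def gsr_features(gsr_filtered, rate: float, min_amp: float = SCR_MIN_AMP
                 ) -> dict[str, float]:
    tonic, phasic = gsr_decompose(gsr_filtered, rate)
    n1 = int(rate)
    count, amp_mean, amp_std = scr_score(phasic, rate, min_amp)
    return dict(
        gsr_tonic_mean=float(np.mean(tonic)),
        gsr_tonic_delta=float(np.mean(tonic[-n1:]) - np.mean(tonic[:n1])),
        scr_count=float(count), scr_amp_mean=amp_mean, scr_amp_std=amp_std,
    )


# ---------------------------------------------------------------------------
# Assembled per-epoch extractors
# ---------------------------------------------------------------------------

def physio_features(ep: Epoch, min_amp: float = SCR_MIN_AMP) -> dict[str, float]:
    """All 17 physiological features for one (already filtered) epoch."""
    rate = ep.physio_rate
    out: dict[str, float] = {}
    out.update(respiration_features(ep.physio["resp"].to_numpy(), rate))
    out.update(st_features(ep.physio["st"].to_numpy(), rate))
    out.update(gsr_features(ep.physio["gsr"].to_numpy(), rate, min_amp))
    ecg = ep.physio["ecg"].to_numpy()
    beats = detect_r_peaks(ecg, rate)
    out.update(ecg_features(ecg, beats, rate))
    return {k: out[k] for k in PHYSIO_FEATURES}


def kinematics_features(kin_epoch: pd.DataFrame) -> dict[str, float]:
    """Mean, std and fluctuation (mean |first difference|) per channel."""
    missing = [ch for ch in KIN_CHANNELS if ch not in kin_epoch.columns]
    if missing:
        raise ValueError(f"missing kinematics channels: {', '.join(missing)}")
    out = {}
    for ch in KIN_CHANNELS:
        x = kin_epoch[ch].to_numpy(dtype=float)
        out[f"{ch}_mean"] = float(np.mean(x))
        out[f"{ch}_std"] = float(np.std(x, ddof=0))
        out[f"{ch}_fluct"] = float(np.mean(np.abs(np.diff(x)))) if x.size > 1 else 0.0
    return out


def encode_characteristics(questionnaires: dict, participant: int, session: int
                           ) -> dict[str, float]:
    """The 20 driver-characteristics values for one session.

    Six demographics, five personality traits, perceived stress, four mood
    scales, and four extras (BMI, glasses flag, session start hour, session
    ordinal).  Identical for every scenario of the session.
    """
    try:
        part = questionnaires["participants"][participant]
        sess = part["sessions"][session]
    except KeyError as e:
        raise KeyError(
            f"questionnaires missing for participant {participant}, session {session}"
        ) from e
    demo = part["demographics"]
    out = dict(
        age=demo["age"], gender=demo["gender"], dominant_hand=demo["dominant_hand"],
        driving_experience=demo["driving_experience"], height=demo["height"],
        weight=demo["weight"],
    )
    out.update({f"ipip_{t}": part["ipip"][t] for t in IPIP_TRAITS})
    out["pss10"] = part["pss10"]
    out.update({f"staq_{s}": sess["staq"][s] for s in STAQ_SCALES})
    out["bmi"] = demo["weight"] / (demo["height"] / 100.0) ** 2
    out["glasses"] = demo["glasses"]
    out["session_start_hour"] = sess["start_hour"]
    out["session_ordinal"] = float(session)
    return {k: float(out[k]) for k in CHARACTERISTICS_FEATURES}


def extract_features(study, min_amp: float = SCR_MIN_AMP) -> pd.DataFrame:
    """Feature table for a whole study: one row per epoch (baseline rows
    carry only the physiological block, used later for baseline
    subtraction), 61 feature columns plus ids and the four cause labels."""
    rows = []
    for p, s in study.sessions():
        rec = study.session_recording(p, s)
        chars = encode_characteristics(study.questionnaires, p, s)
        for ep in _epoch(rec):
            row = dict(participant=ep.participant, session=ep.session,
                       segment=ep.segment, role=ep.role)
            if ep.labels is not None:
                row.update(ep.labels.as_dict())
            else:
                seg_row = rec.segments[rec.segments["segment"] == ep.segment].iloc[0]
                row.update({c: int(seg_row[c]) for c in CAUSES})
            row.update(physio_features(ep, min_amp))
            if ep.role == "scenario" and ep.kinematics is not None:
                row.update(kinematics_features(ep.kinematics))
            row.update(chars)
            rows.append(row)
    cols = list(ID_COLUMNS) + list(CAUSES) + list(ALL_FEATURES)
    return pd.DataFrame(rows).reindex(columns=cols)
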