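"""Synthetic multimodal study generator.

Produces a complete synthetic driving study — raw physiology (ECG,
respiration, skin conductance, skin temperature) at the physio sampling
rate, eight vehicle-kinematics channels at the kinematics rate, and
questionnaire scores — with the factorial structure of
:class:`~hdscause.design.StudyDesign` and condition effects from
:class:`~hdscause.design.EffectConfig`.

The waveform models are deliberately simple, parameter-transparent
plumbing: every effect a downstream feature extractor is supposed to pick
up is injected through a named generator parameter, so extractors can be
tested by parameter recovery.  None of the models aim at morphological
realism (no PQRST complex, no vehicle dynamics).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .design import CAUSES, ConditionLabels, EffectConfig, StudyDesign, labels_from_row

__all__ = [
    "KIN_CHANNELS", "PHYSIO_CHANNELS", "SessionRecording", "SyntheticStudy",
    "synth_ecg", "synth_gsr", "synth_resp", "synth_st", "synth_kinematics",
    "simulate_questionnaires", "simulate_study", "write_study", "load_study",
    "tlx_table",
]

PHYSIO_CHANNELS = ("ecg", "resp", "gsr", "st")
#: Vehicle kinematics channel order (fixed; feature names derive from it).
KIN_CHANNELS = (
    "throttle", "lane_number", "lat_pos", "road_offset",
    "long_vel", "vert_vel", "slip_front", "slip_rear",
)

TLX_SUBSCALES = ("mental", "physical", "temporal", "performance", "effort", "frustration")
STAQ_SCALES = ("negative", "positive", "activated", "inactivated")
IPIP_TRAITS = ("extraversion", "neuroticism", "agreeableness", "openness", "conscientiousness")

# Neutral-scenario generator settings (per-channel baselines before
# participant offsets and condition effects are applied).
NEUTRAL = dict(
    mean_hr=75.0,        # beats/min
    lf_amp=0.008,        # s, 0.10 Hz IBI modulation depth
    hf_amp=0.010,        # s, respiratory IBI modulation depth
    artifact_power=0.0,  # mV, broadband motion-burst amplitude
    resp_rate=15.0,      # breaths/min
    tonic_mean=5.0,      # uS
    tonic_slope=0.0,     # uS/s
    scr_amp_mean=0.40,   # uS
    scr_amp_std=0.10,    # uS
    st_mean=33.0,        # degC
    lat_pos_mean=0.0,    # m
    lane_std=0.11,       # lane-number std in light traffic
    throttle_std=5.0,
    slip_mean=0.0,
    slip_std=1.0,        # multiplier on the per-channel base slip scale
)


# ---------------------------------------------------------------------------
# Elementary waveform generators
# ---------------------------------------------------------------------------

def _ou(n: int, dt: float, mean: float, sd: float, tau: float, rng) -> np.ndarray:
    """Stationary mean-reverting (AR(1)) noise with sd ``sd`` and time constant ``tau``."""
    a = np.exp(-dt / tau)
    innov_sd = sd * np.sqrt(1.0 - a * a)
    eps = rng.normal(0.0, innov_sd, n)
    x = signal.lfilter([1.0], [1.0, -a], eps)
    x[0] = rng.normal(0.0, sd)
    return mean + x


def _beat_times(duration, mean_hr, lf_amp, hf_amp, ibi_noise, mayer_freq, resp_freq, rng):
    """Inter-beat interval series: base IBI plus LF/HF sinusoidal modulation."""
    base = 60.0 / mean_hr
    times = []
    t = float(rng.uniform(0.0, base))
    while t < duration:
        times.append(t)
        ibi = (
            base
            + lf_amp * np.sin(2 * np.pi * mayer_freq * t)
            + hf_amp * np.sin(2 * np.pi * resp_freq * t)
            + (rng.normal(0.0, ibi_noise) if ibi_noise > 0 else 0.0)
        )
        t += max(ibi, 0.25)  # physiological refractory floor
    return np.asarray(times)


def synth_ecg(duration, rate, mean_hr, lf_amp=0.0, hf_amp=0.0, artifact_power=0.0,
              ibi_noise=0.0, mayer_freq=0.10, resp_freq=0.25, rng=None):
    """Synthetic ECG: narrow QRS-like pulses at modulated inter-beat intervals.

    Beats are Gaussian pulses (sigma 8 ms, 1 mV) placed at times whose
    spacing is ``60/mean_hr`` plus sinusoidal low-frequency (``mayer_freq``)
    and respiratory (``resp_freq``) modulation and Gaussian jitter.
    ``artifact_power`` adds broadband half-second bursts emulating motion
    artifacts from arm gestures.
    """
    if not 30.0 <= mean_hr <= 200.0:
        raise ValueError(f"mean_hr must lie in [30, 200] beats/min, got {mean_hr}")
    if duration < 2 * 60.0 / mean_hr:
        raise ValueError("duration too short to contain two beats")
    rng = np.random.default_rng(rng)
    n = int(round(duration * rate))
    beats = _beat_times(duration, mean_hr, lf_amp, hf_amp, ibi_noise,
                        mayer_freq, resp_freq, rng)
    x = np.zeros(n)
    idx = np.round(beats * rate).astype(int)
    idx = idx[idx < n]
    x[idx] = 1.0
    half = int(round(0.030 * rate))
    tt = np.arange(-half, half + 1) / rate
    template = np.exp(-0.5 * (tt / 0.008) ** 2)  # sigma 8 ms
    x = signal.fftconvolve(x, template, mode="same")
    x += rng.normal(0.0, 0.01, n)  # sensor noise floor
    if artifact_power > 0:
        burst_rate = 6.0 / 60.0  # bursts per second when gesturing
        n_bursts = rng.poisson(burst_rate * duration)
        w = int(round(0.5 * rate))
        win = np.hanning(w)
        for t0 in rng.uniform(0, duration - 0.5, n_bursts):
            i0 = int(t0 * rate)
            x[i0:i0 + w] += artifact_power * win[: len(x[i0:i0 + w])] * \
                rng.normal(0.0, 1.0, len(x[i0:i0 + w]))
    return x


def synth_resp(duration, rate, resp_rate_bpm, amp=1.0, jitter=0.02, noise=0.05, rng=None):
    """Respiration belt signal: near-sinusoidal with slowly drifting rate."""
    if resp_rate_bpm <= 0:
        raise ValueError("resp_rate_bpm must be positive")
    rng = np.random.default_rng(rng)
    n = int(round(duration * rate))
    dt = 1.0 / rate
    f0 = resp_rate_bpm / 60.0
    finst = f0 * (1.0 + _ou(n, dt, 0.0, jitter, 20.0, rng))
    phase = 2 * np.pi * np.cumsum(finst) * dt
    return amp * np.sin(phase) + rng.normal(0.0, noise, n)


_SCR_TAU_RISE = 0.7   # s
_SCR_TAU_DECAY = 3.0  # s


def _scr_kernel(rate: float) -> np.ndarray:
    t = np.arange(0, 20.0, 1.0 / rate)
    k = np.exp(-t / _SCR_TAU_DECAY) - np.exp(-t / _SCR_TAU_RISE)
    return k / k.max()  # unit peak -> amplitudes are in uS


def synth_gsr(duration, rate, tonic_level, tonic_slope=0.0,
              scr_times=(), scr_amps=(), noise=0.005, rng=None):
    """Skin conductance: linear tonic drift plus bi-exponential phasic pulses.

    Each pulse rises within ~1 s and decays over ~4 s to emulate a discrete
    sweat-gland response; ``scr_amps`` are trough-to-peak amplitudes in uS.
    """
    scr_times = np.asarray(scr_times, dtype=float)
    scr_amps = np.asarray(scr_amps, dtype=float)
    if scr_times.size != scr_amps.size:
        raise ValueError("scr_times and scr_amps must have equal length")
    if np.any(scr_amps < 0):
        raise ValueError("SCR amplitudes must be non-negative")
    if scr_times.size and (scr_times.min() < 0 or scr_times.max() >= duration):
        raise ValueError("scr_times must lie within [0, duration)")
    rng = np.random.default_rng(rng)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    x = tonic_level + tonic_slope * t
    if scr_times.size:
        impulses = np.zeros(n)
        idx = np.minimum(np.round(scr_times * rate).astype(int), n - 1)
        np.add.at(impulses, idx, scr_amps)
        x = x + signal.fftconvolve(impulses, _scr_kernel(rate))[:n]
    if noise > 0:
        x = x + rng.normal(0.0, noise, n)
    return x


def synth_st(duration, rate, st_mean, drift=0.0, noise=0.005, rng=None):
    """Skin temperature: slow mean level with optional linear drift."""
    rng = np.random.default_rng(rng)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    return st_mean + drift * t + _ou(n, 1.0 / rate, 0.0, 0.05, 60.0, rng) \
        + rng.normal(0.0, noise, n)


def _telegraph(n, dt, occupancy, mean_dwell_high, rng):
    """0/1 semi-Markov lane process with stationary P(lane=1)=occupancy."""
    occupancy = float(np.clip(occupancy, 1e-4, 0.5))
    d1 = mean_dwell_high
    d0 = d1 * (1.0 - occupancy) / occupancy
    x = np.zeros(n, dtype=float)
    state = 1 if rng.random() < occupancy else 0
    i = 0
    while i < n:
        dwell = rng.exponential(d1 if state else d0)
        j = min(n, i + max(1, int(round(dwell / dt))))
        x[i:j] = state
        state = 1 - state
        i = j
    return x


def synth_kinematics(duration, rate, labels: ConditionLabels,
                     effects: EffectConfig | None = None, rng=None,
                     wander: dict | None = None) -> pd.DataFrame:
    """Eight vehicle-kinematics channels for one scenario.

    Throttle, velocities and lateral offsets are mean-reverting noise; lane
    number is a 0/1 telegraph process whose standard deviation scales with
    the town (dense-traffic) effect; tire-slip channels sit near zero in
    clear weather and gain mean and variance in snow, scaled by how far the
    road friction drops (``snow_friction_factor``).
    """
    effects = effects or EffectConfig()
    rng = np.random.default_rng(rng)
    n = int(round(duration * rate))
    dt = 1.0 / rate
    sh = lambda p, b: effects.shifted(labels, p, b)

    throttle = _ou(n, dt, 30.0, sh("throttle_std", NEUTRAL["throttle_std"]), 3.0, rng)
    # lane occupancy solved from the target std so std scales linearly with
    # the town multiplier: std = base_lane_std * mult (capped below 0.5)
    lane_std = min(sh("lane_std", NEUTRAL["lane_std"]), 0.497)
    occupancy = 0.5 * (1.0 - np.sqrt(max(1.0 - 4.0 * lane_std ** 2, 0.0)))
    # dwell chosen so even low occupancy yields a few excursions per epoch
    # (keeps the per-epoch std close to its stationary value)
    dwell = float(np.clip(occupancy * duration / 3.0, 1.0, 8.0))
    lane = _telegraph(n, dt, occupancy, dwell, rng)
    lat_base = NEUTRAL["lat_pos_mean"] + (wander or {}).get("lat_pos_mean", 0.0)
    lat_pos = _ou(n, dt, sh("lat_pos_mean", lat_base), 0.25, 5.0, rng)
    road_offset = lat_pos + 3.6 * (lane - 0.5) + rng.normal(0, 0.02, n)
    long_vel = _ou(n, dt, 30.0, 2.0, 10.0, rng)
    vert_vel = _ou(n, dt, 0.0, 0.05, 1.0, rng)

    severity = (1.0 - effects.snow_friction_factor) / 0.4  # 1.0 at the 60% default
    slip_mean = sh("slip_mean", NEUTRAL["slip_mean"]) * severity
    slip_std_mult = 1.0 + (sh("slip_std", NEUTRAL["slip_std"]) - 1.0) * severity
    base_scale = 0.01
    slip_front = np.abs(_ou(n, dt, 0.6 * slip_mean, 0.6 * base_scale * slip_std_mult, 0.5, rng))
    slip_rear = np.abs(_ou(n, dt, slip_mean, base_scale * slip_std_mult, 0.5, rng))
    data = dict(
        throttle=throttle, lane_number=lane, lat_pos=lat_pos,
        road_offset=road_offset, long_vel=long_vel, vert_vel=vert_vel,
        slip_front=np.clip(slip_front, 0.0, 1.0),
        slip_rear=np.clip(slip_rear, 0.0, 1.0),
    )
    return pd.DataFrame(data, columns=list(KIN_CHANNELS))


# ---------------------------------------------------------------------------
# Questionnaires
# ---------------------------------------------------------------------------

def _clip(x, lo, hi):
    return float(np.clip(x, lo, hi))


def simulate_questionnaires(design: StudyDesign, effects: EffectConfig,
                            segments: pd.DataFrame, rng) -> dict:
    """Demographics, personality (IPIP), stress (PSS-10), mood (STAQ) and
    per-scenario workload (NASA-TLX) for every participant.

    Scores are Gaussian around condition-shifted means, truncated to each
    instrument's scale range.  Drowsy sessions shift the mood scales; each
    active cause adds its configured shift to the TLX subscales.
    """
    out: dict = {"participants": {}}
    for p in sorted(segments["participant"].unique()):
        demo = dict(
            age=_clip(rng.normal(25.1, 8.7), 18, 65),
            gender=int(rng.random() < 6 / 21),        # 1 = female
            dominant_hand=int(rng.random() < 0.1),    # 1 = left
            height=_clip(rng.normal(172, 9), 150, 200),
            weight=_clip(rng.normal(72, 12), 45, 120),
            glasses=int(rng.random() < 0.35),
        )
        demo["driving_experience"] = _clip(demo["age"] - 18 - abs(rng.normal(1, 1.5)), 0.5, 40)
        ipip = {t: _clip(rng.normal(50, 10), 0, 100) for t in IPIP_TRAITS}
        pss10 = _clip(rng.normal(15, 6), 0, 40)
        sessions: dict = {}
        for s in sorted(segments.loc[segments["participant"] == p, "session"].unique()):
            seg = segments[(segments["participant"] == p) & (segments["session"] == s)]
            drowsy = int(seg["drowsy"].iloc[0])
            lab_session = ConditionLabels(phone=0, drowsy=drowsy, town=0, snowy=0)
            staq_base = dict(negative=30.0, positive=60.0, activated=50.0, inactivated=40.0)
            staq = {
                k: _clip(rng.normal(effects.shifted(lab_session, f"staq_{k}", v), 6), 0, 100)
                for k, v in staq_base.items()
            }
            start_hour = float(effects.shifted(
                lab_session, "start_hour", rng.uniform(13, 16)))
            part_shift = rng.normal(0, 6)  # participant x session workload disposition
            tlx: dict = {}
            for _, row in seg[seg["role"] == "scenario"].iterrows():
                lab = labels_from_row(row)
                scores = {
                    sub: _clip(rng.normal(
                        effects.shifted(lab, f"tlx_{sub}", 40.0) + part_shift, 10), 0, 100)
                    for sub in TLX_SUBSCALES
                }
                scores["overall"] = float(np.mean([scores[s_] for s_ in TLX_SUBSCALES]))
                tlx[int(row["segment"])] = scores
            sessions[int(s)] = dict(staq=staq, start_hour=start_hour, nasa_tlx=tlx)
        out["participants"][int(p)] = dict(
            demographics=demo, ipip=ipip, pss10=pss10, sessions=sessions)
    return out


def tlx_table(questionnaires: dict, segments: pd.DataFrame) -> pd.DataFrame:
    """Long-format NASA-TLX table: one row per scenario with cause labels."""
    rows = []
    for _, row in segments[segments["role"] == "scenario"].iterrows():
        p, s, k = int(row["participant"]), int(row["session"]), int(row["segment"])
        scores = questionnaires["participants"][p]["sessions"][s]["nasa_tlx"][k]
        rows.append({
            "participant": p, "session": s, "segment": k,
            **{c: int(row[c]) for c in CAUSES},
            **scores,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-study simulation
# ---------------------------------------------------------------------------

@dataclass
class SessionRecording:
    """One continuous session: baseline followed by the scenario segments."""

    participant: int
    session: int
    physio: pd.DataFrame        # columns ecg, resp, gsr, st
    physio_rate: float
    kinematics: pd.DataFrame    # the 8 KIN_CHANNELS columns
    kinematics_rate: float
    segments: pd.DataFrame      # rows of the study layout for this session


class SyntheticStudy:
    """Lazy handle on a simulated study.

    The segment table and questionnaires are materialised eagerly (they are
    small); raw session waveforms are synthesised on demand from a seed
    derived deterministically from ``(design.seed, participant, session)``,
    so repeated access — and repeated simulation with the same seed — is
    byte-identical without holding gigabytes in memory.
    """

    def __init__(self, design: StudyDesign, effects: EffectConfig | None = None):
        self.design = design
        self.effects = effects or EffectConfig()
        self.segments = design.layout()
        root = np.random.SeedSequence(design.seed)
        # stable participant-level physiology offsets
        prng = np.random.default_rng(np.random.SeedSequence(design.seed, spawn_key=(0,)))
        self._offsets = {
            p: dict(
                hr=prng.normal(0, 6), tonic=prng.normal(0, 0.8),
                resp=prng.normal(0, 1.5), st=prng.normal(0, 0.4),
            )
            for p in range(1, design.n_participants + 1)
        }
        qrng = np.random.default_rng(np.random.SeedSequence(design.seed, spawn_key=(1,)))
        self.questionnaires = simulate_questionnaires(
            design, self.effects, self.segments, qrng)
        self._root = root

    # -- iteration ---------------------------------------------------------
    def sessions(self):
        for p in range(1, self.design.n_participants + 1):
            for s in range(1, self.design.n_sessions_per_participant + 1):
                yield p, s

    def session_recording(self, participant: int, session: int) -> SessionRecording:
        design, effects = self.design, self.effects
        seg = self.segments[
            (self.segments["participant"] == participant)
            & (self.segments["session"] == session)
        ].sort_values("segment")
        if seg.empty:
            raise KeyError(f"no session {session} for participant {participant}")
        rng = np.random.default_rng(
            np.random.SeedSequence(design.seed, spawn_key=(2, participant, session)))
        off = self._offsets[participant]
        phys, kin = [], []
        for _, row in seg.iterrows():
            lab = labels_from_row(row)
            dur = row["end_s"] - row["start_s"]
            sh = lambda p_, b: effects.shifted(lab, p_, b)
            # slow physiological wander between segments of a session
            w = {k: rng.normal(0.0, sd) for k, sd in effects.scenario_wander.items()}
            ecg = synth_ecg(
                dur, design.physio_rate,
                mean_hr=np.clip(NEUTRAL["mean_hr"] + off["hr"] + w["mean_hr"], 40, 180),
                lf_amp=sh("lf_amp", NEUTRAL["lf_amp"]),
                hf_amp=sh("hf_amp", NEUTRAL["hf_amp"]),
                artifact_power=sh("artifact_power", NEUTRAL["artifact_power"]),
                ibi_noise=effects.noise["ibi"], mayer_freq=effects.mayer_freq,
                resp_freq=effects.resp_freq, rng=rng)
            resp = synth_resp(
                dur, design.physio_rate,
                resp_rate_bpm=sh("resp_rate",
                                 NEUTRAL["resp_rate"] + off["resp"] + w["resp_rate"]),
                noise=effects.noise["resp"], rng=rng)
            n_scr = rng.poisson(effects.scr_rate * dur / 60.0)
            scr_t = np.sort(rng.uniform(0, dur - 1e-6, n_scr))
            amp_mean = sh("scr_amp_mean", NEUTRAL["scr_amp_mean"])
            amp_std = sh("scr_amp_std", NEUTRAL["scr_amp_std"])
            scr_a = np.clip(rng.normal(amp_mean, amp_std, n_scr), 0.08, None)
            gsr = synth_gsr(
                dur, design.physio_rate,
                tonic_level=sh("tonic_mean",
                               NEUTRAL["tonic_mean"] + off["tonic"] + w["tonic_mean"]),
                tonic_slope=sh("tonic_slope", NEUTRAL["tonic_slope"]),
                scr_times=scr_t, scr_amps=scr_a,
                noise=effects.noise["gsr"], rng=rng)
            st = synth_st(dur, design.physio_rate,
                          NEUTRAL["st_mean"] + off["st"] + w["st_mean"],
                          drift=rng.normal(0, 2e-4), noise=effects.noise["st"], rng=rng)
            phys.append(pd.DataFrame(dict(ecg=ecg, resp=resp, gsr=gsr, st=st)))
            kin.append(synth_kinematics(dur, design.kinematics_rate, lab, effects,
                                        rng, wander=w))
        return SessionRecording(
            participant=participant, session=session,
            physio=pd.concat(phys, ignore_index=True), physio_rate=design.physio_rate,
            kinematics=pd.concat(kin, ignore_index=True),
            kinematics_rate=design.kinematics_rate,
            segments=seg.reset_index(drop=True),
        )


def simulate_study(design: StudyDesign, effects: EffectConfig | None = None) -> SyntheticStudy:
    """Simulate a full study; see :class:`SyntheticStudy` for lazy semantics."""
    design.validate()
    return SyntheticStudy(design, effects)


# ---------------------------------------------------------------------------
# Disk layout
# ---------------------------------------------------------------------------

def write_study(study: SyntheticStudy, outdir: str | Path) -> Path:
    """Write the study as one directory per participant/session.

    Layout: ``p<P>/s<S>/physio.csv`` (t_s, ecg, resp, gsr, st),
    ``kinematics.csv`` (t_s + the 8 channels), ``segments.csv`` and a
    per-participant ``questionnaires.json``; a top-level ``manifest.json``
    records design, seed and effect configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = dict(design=study.design.as_dict(), effects=study.effects.as_dict(),
                    seed=study.design.seed)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for p, s in study.sessions():
        rec = study.session_recording(p, s)
        d = outdir / f"p{p:02d}" / f"s{s}"
        d.mkdir(parents=True, exist_ok=True)
        phys = rec.physio.copy()
        phys.insert(0, "t_s", np.arange(len(phys)) / rec.physio_rate)
        phys.to_csv(d / "physio.csv", index=False, float_format="%.5f")
        kin = rec.kinematics.copy()
        kin.insert(0, "t_s", np.arange(len(kin)) / rec.kinematics_rate)
        kin.to_csv(d / "kinematics.csv", index=False, float_format="%.5f")
        rec.segments.to_csv(d / "segments.csv", index=False)
        qpath = outdir / f"p{p:02d}" / "questionnaires.json"
        if not qpath.exists():
            qpath.write_text(json.dumps(
                study.questionnaires["participants"][p], indent=2))
    return outdir


class LoadedStudy:
    """Study read back from the on-disk layout; duck-types SyntheticStudy."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        manifest = json.loads((self.root / "manifest.json").read_text())
        d = manifest["design"]
        self.design = StudyDesign(**d)
        eff = manifest["effects"]
        self.effects = EffectConfig(**eff)
        segs, q = [], {"participants": {}}
        for pdir in sorted(self.root.glob("p*")):
            p = int(pdir.name[1:])
            q["participants"][p] = json.loads((pdir / "questionnaires.json").read_text())
            # JSON round-trip stringifies the int keys
            for s, sess in list(q["participants"][p].get("sessions", {}).items()):
                sess["nasa_tlx"] = {int(k): v for k, v in sess["nasa_tlx"].items()}
                q["participants"][p]["sessions"] = {
                    int(k): v for k, v in q["participants"][p]["sessions"].items()}
            for sdir in sorted(pdir.glob("s*")):
                segs.append(pd.read_csv(sdir / "segments.csv"))
        self.segments = pd.concat(segs, ignore_index=True)
        self.questionnaires = q

    def sessions(self):
        pairs = self.segments[["participant", "session"]].drop_duplicates()
        for _, r in pairs.iterrows():
            yield int(r["participant"]), int(r["session"])

    def session_recording(self, participant: int, session: int) -> SessionRecording:
        d = self.root / f"p{participant:02d}" / f"s{session}"
        phys = pd.read_csv(d / "physio.csv").drop(columns=["t_s"])
        kin = pd.read_csv(d / "kinematics.csv").drop(columns=["t_s"])
        seg = pd.read_csv(d / "segments.csv")
        return SessionRecording(
            participant=participant, session=session,
            physio=phys, physio_rate=self.design.physio_rate,
            kinematics=kin, kinematics_rate=self.design.kinematics_rate,
            segments=seg,
        )


def load_study(root: str | Path) -> LoadedStudy:
    return LoadedStudy(root)
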