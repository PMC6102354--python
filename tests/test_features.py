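import numpy as np
import pandas as pd
import pytest
from scipy import signal

from hdscause.features import (ALL_FEATURES, CHARACTERISTICS_FEATURES,
                               KINEMATICS_FEATURES, PHYSIO_FEATURES,
                               detect_r_peaks, ecg_features,
                               encode_characteristics, gsr_decompose,
                               kinematics_features, respiration_features,
                               scr_score, st_features)
from hdscause.preprocessing import filter_ecg, filter_lowband
from hdscause.simulate import KIN_CHANNELS, synth_ecg, synth_gsr


def test_feature_count_contract():
    assert len(PHYSIO_FEATURES) == 17
    assert len(KINEMATICS_FEATURES) == 24
    assert len(CHARACTERISTICS_FEATURES) == 20
    assert len(ALL_FEATURES) == 61
    assert len(set(ALL_FEATURES)) == 61


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

class TestRPeaks:
    def test_clean_ecg_beat_count(self):
        x = filter_ecg(synth_ecg(240, 256, mean_hr=60, rng=0), 256)
        beats = detect_r_peaks(x, 256)
        assert abs(len(beats) - 240) <= 2

    @pytest.mark.parametrize("seed", range(5))
    def test_mean_hr_recovered_within_1bpm(self, seed):
        hr = 55 + 10 * seed
        x = filter_ecg(synth_ecg(240, 256, mean_hr=hr, lf_amp=0.01, hf_amp=0.01,
                                 ibi_noise=0.01, rng=seed), 256)
        beats = detect_r_peaks(x, 256)
        est = 60.0 / np.mean(np.diff(beats))
        assert est == pytest.approx(hr, abs=1.0)

    def test_refractory_period_enforced(self):
        x = filter_ecg(synth_ecg(120, 512, mean_hr=180, rng=1), 512)
        beats = detect_r_peaks(x, 512)
        assert np.all(np.diff(beats) >= 0.25)
        assert np.all(np.diff(beats) > 0)

    def test_flat_signal_flags_missing(self):
        beats = detect_r_peaks(np.zeros(256 * 30), 256)
        feats = ecg_features(np.zeros(256 * 30), beats, 256)
        assert np.isnan(feats["hr_mean"]) and np.isnan(feats["lf_hf_ratio"])


class TestEcgFeatures:
    def test_constant_ibi(self):
        beats = np.arange(0, 240, 1.0)
        feats = ecg_features(np.zeros(240 * 64), beats, 64)
        assert feats["hr_mean"] == pytest.approx(60.0)
        assert feats["ibi_std"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("freq,check", [(0.10, "lf"), (0.30, "hf")])
    def test_single_band_modulation_dominates_ratio(self, freq, check):
        """Periodogram oracle: IBI modulated only inside one band pushes the
        LF/HF power ratio to that band's side."""
        t, beats = 0.0, []
        while t < 300:
            beats.append(t)
            t += 1.0 + 0.05 * np.sin(2 * np.pi * freq * t)
        feats = ecg_features(np.zeros(10), np.asarray(beats), 64)
        if check == "lf":
            assert feats["lf_hf_ratio"] > 5
        else:
            assert feats["lf_hf_ratio"] < 0.2

    def test_gradient_features_rate_invariant_units(self):
        rng = np.random.default_rng(0)
        hi = filter_lowband(rng.normal(size=512 * 30), 512)
        f_hi = ecg_features(hi, np.array([]), 512)
        lo = hi[::4]  # same waveform at quarter rate
        f_lo = ecg_features(lo, np.array([]), 128)
        assert f_lo["ecg_grad_absmean"] == pytest.approx(
            f_hi["ecg_grad_absmean"], rel=0.15)


# ---------------------------------------------------------------------------
# Respiration
# ---------------------------------------------------------------------------

class TestRespiration:
    def test_quarter_hz_sinusoid_gives_15_bpm(self):
        t = np.arange(240 * 64) / 64
        x = np.sin(2 * np.pi * 0.25 * t)
        feats = respiration_features(x, 64)
        assert feats["rr_mean"] == pytest.approx(15.0, abs=0.3)

    def test_strictly_periodic_breathing_rmssd_zero(self):
        t = np.arange(240 * 64) / 64
        feats = respiration_features(np.sin(2 * np.pi * 0.25 * t), 64)
        assert feats["rr_rmssd"] == pytest.approx(0.0, abs=0.02)

    def test_alternating_periods_rmssd_two_seconds(self):
        """Breath periods 3,5,3,5,... s: successive differences are +-2 s, so
        the RMS of successive differences is exactly 2."""
        rate = 64
        periods = [3.0, 5.0] * 20
        times = np.cumsum([2.0] + periods)
        n = int((times[-1] + 3) * rate)
        x = np.zeros(n)
        tt = np.arange(n) / rate
        for c in times:
            x += np.exp(-0.5 * ((tt - c) / 0.4) ** 2)
        feats = respiration_features(x, rate)
        assert feats["rr_rmssd"] == pytest.approx(2.0, abs=0.05)

    def test_too_few_cycles_flags_missing(self):
        x = np.zeros(64 * 30)
        feats = respiration_features(x, 64)
        assert np.isnan(feats["rr_mean"])


# ---------------------------------------------------------------------------
# Skin temperature
# ---------------------------------------------------------------------------

class TestSkinTemperature:
    def test_constant(self):
        f = st_features(np.full(64 * 10, 33.0), 64)
        assert f["st_mean"] == pytest.approx(33.0)
        assert f["st_delta"] == pytest.approx(0.0)

    def test_linear_ramp_delta(self):
        x = np.linspace(33.0, 33.5, 64 * 240)
        f = st_features(x, 64)
        assert f["st_delta"] == pytest.approx(0.5, abs=0.01)

    def test_reversed_ramp_flips_sign(self):
        x = np.linspace(33.5, 33.0, 64 * 240)
        assert st_features(x, 64)["st_delta"] == pytest.approx(-0.5, abs=0.01)

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            st_features(np.zeros(10), 64)


# ---------------------------------------------------------------------------
# Skin conductance
# ---------------------------------------------------------------------------

class TestGsr:
    def test_reconstruction_is_exact(self):
        x = synth_gsr(120, 64, 5.0, 0.001, scr_times=[30, 80], scr_amps=[0.5, 0.3],
                      rng=0)
        tonic, phasic = gsr_decompose(x, 64)
        assert np.max(np.abs(x - (tonic + phasic))) < 1e-12

    def test_pure_slope_has_no_phasic(self):
        t = np.arange(120 * 64) / 64
        _, phasic = gsr_decompose(5.0 + 0.01 * t, 64)
        assert np.max(np.abs(phasic)) < 0.01

    def test_injected_pulse_lands_in_phasic(self):
        """A generator-known pulse keeps >=90% of its (trough-to-peak)
        amplitude in the phasic component; absolute peak level is partly
        shared with the tonic since a slow pulse has sub-0.05 Hz content."""
        x = synth_gsr(120, 64, 5.0, scr_times=[60.0], scr_amps=[1.0], noise=0.0)
        _, phasic = gsr_decompose(x, 64)
        pk = int(np.argmax(phasic))
        trough = phasic[max(0, pk - 5 * 64):pk].min()
        assert phasic[pk] - trough >= 0.90
        assert phasic[pk] >= 0.5

    def test_scr_recovery_count_and_amplitude(self):
        """Recovery oracle: 5 injected 0.5 uS responses at low noise."""
        times = [20, 60, 100, 140, 180]
        x = synth_gsr(220, 64, 5.0, scr_times=times, scr_amps=[0.5] * 5,
                      noise=0.002, rng=1)
        _, phasic = gsr_decompose(filter_lowband(x, 64), 64)
        count, amp_mean, amp_std = scr_score(phasic, 64)
        assert count == 5
        assert amp_mean == pytest.approx(0.5, abs=0.06)
        assert amp_std == pytest.approx(0.0, abs=0.03)

    def test_two_amplitudes_average(self):
        x = synth_gsr(120, 64, 5.0, scr_times=[30, 80], scr_amps=[0.2, 0.4],
                      noise=0.002, rng=2)
        _, phasic = gsr_decompose(filter_lowband(x, 64), 64)
        count, amp_mean, _ = scr_score(phasic, 64)
        assert count == 2
        assert amp_mean == pytest.approx(0.3, abs=0.04)

    def test_no_events_flags_missing(self):
        x = synth_gsr(60, 64, 5.0, noise=0.002, rng=3)
        _, phasic = gsr_decompose(filter_lowband(x, 64), 64)
        count, amp_mean, amp_std = scr_score(phasic, 64)
        assert count == 0
        assert np.isnan(amp_mean) and np.isnan(amp_std)

    def test_min_amp_must_be_positive(self):
        with pytest.raises(ValueError, match="min_amp"):
            scr_score(np.zeros(100), 64, min_amp=0.0)


# ---------------------------------------------------------------------------
# Kinematics and characteristics
# ---------------------------------------------------------------------------

class TestKinematicsFeatures:
    def test_constant_channels_zero_spread(self):
        df = pd.DataFrame({ch: np.full(100, i) for i, ch in enumerate(KIN_CHANNELS)})
        f = kinematics_features(df)
        assert len(f) == 24
        for ch in KIN_CHANNELS:
            assert f[f"{ch}_std"] == 0.0
            assert f[f"{ch}_fluct"] == 0.0

    def test_alternating_lane_fluctuation_is_one(self):
        df = pd.DataFrame({ch: np.zeros(100) for ch in KIN_CHANNELS})
        df["lane_number"] = np.arange(100) % 2
        assert kinematics_features(df)["lane_number_fluct"] == pytest.approx(1.0)

    def test_missing_channel_named_in_error(self):
        df = pd.DataFrame({ch: np.zeros(10) for ch in KIN_CHANNELS[:-1]})
        with pytest.raises(ValueError, match="slip_rear"):
            kinematics_features(df)


class TestCharacteristics:
    def test_vector_length_and_session_constancy(self, small_study):
        a = encode_characteristics(small_study.questionnaires, 1, 1)
        b = encode_characteristics(small_study.questionnaires, 1, 1)
        assert len(a) == 20 and a == b
        assert list(a) == list(CHARACTERISTICS_FEATURES)

    def test_drowsy_alert_sessions_differ_in_negative_affect(self, small_study):
        seg = small_study.segments
        drowsy_flags = seg.groupby(["participant", "session"])["drowsy"].first()
        p = 1
        d_sess = [s for (pp, s), v in drowsy_flags.items() if pp == p and v == 1]
        a_sess = [s for (pp, s), v in drowsy_flags.items() if pp == p and v == 0]
        d = encode_characteristics(small_study.questionnaires, p, d_sess[0])
        a = encode_characteristics(small_study.questionnaires, p, a_sess[0])
        assert d["staq_negative"] != a["staq_negative"]

    def test_missing_questionnaire_rejected(self, small_study):
        with pytest.raises(KeyError, match="participant 99"):
            encode_characteristics(small_study.questionnaires, 99, 1)


# ---------------------------------------------------------------------------
# Whole-table extraction
# ---------------------------------------------------------------------------

class TestExtractFeatures:
    def test_table_shape_and_columns(self, feature_table, small_design):
        scen = feature_table[feature_table["role"] == "scenario"]
        base = feature_table[feature_table["role"] == "baseline"]
        assert len(scen) == small_design.n_scenarios
        assert len(base) == small_design.n_sessions
        assert [c in feature_table.columns for c in ALL_FEATURES].count(True) == 61

    def test_parameter_recovery_in_pipeline(self, feature_table):
        """Extractor means sit near the neutral generator settings: heart
        rate ~75 bpm and breathing ~15/min up to condition shifts."""
        scen = feature_table[feature_table["role"] == "scenario"]
        neutral = scen[(scen["phone"] == 0)]
        assert neutral["hr_mean"].mean() == pytest.approx(75.0, abs=5.0)
        assert neutral["rr_mean"].mean() == pytest.approx(15.0, abs=1.0)
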