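"""Simulate a small synthetic driving study and look at its structure.

Builds a 3-participant study (4 sessions each: 2 drowsy, 2 alert; 1
baseline + 8 scenarios per session covering every traffic/weather/phone
combination), and prints the segment table and one session's raw channels.
"""

import hdscause as h

design = h.StudyDesign(n_participants=3, physio_rate=128.0,
                       kinematics_rate=20.0, seed=1)
study = h.simulate_study(design)

scenarios = study.segments[study.segments["role"] == "scenario"]
print(f"{design.n_participants} participants x "
      f"{design.n_sessions_per_participant} sessions x "
      f"{design.scenarios_per_session} scenarios = {len(scenarios)} scenario rows")
print("\nFirst session layout (labels: 1 = cause present):")
print(study.segments.head(9).to_string(index=False))

rec = study.session_recording(1, 1)
print(f"\nSession recording: physiology {rec.physio.shape} @ "
      f"{rec.physio_rate:.0f} Hz, kinematics {rec.kinematics.shape} @ "
      f"{rec.kinematics_rate:.0f} Hz")
print("Physiology channels:", ", ".join(rec.physio.columns))
print("Kinematics channels:", ", ".join(rec.kinematics.columns))
# The same seed always regenerates byte-identical waveforms, so studies
# can be shared as a (design, effects, seed) triple instead of gigabytes.
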