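import warnings

import pytest

import hdscause as h


@pytest.fixture(scope="session")
def small_design():
    # 3 participants at reduced sampling rates: exercises the full factorial
    # structure while keeping waveform synthesis fast
    return h.StudyDesign(n_participants=3, physio_rate=128.0,
                         kinematics_rate=20.0, seed=7)


@pytest.fixture(scope="session")
def small_study(small_design):
    return h.simulate_study(small_design)


@pytest.fixture(scope="session")
def feature_table(small_study):
    return h.extract_features(small_study)


@pytest.fixture(scope="session")
def normalized_table(feature_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return h.normalize_features(feature_table)
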