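import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sevodoa as sd

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def scaled_spec(duration_s: float = 600.0, **kwargs) -> sd.SessionSpec:
    """Session spec with the standard induction/maintenance/washout profile
    compressed to ``duration_s`` (shorter sessions keep the suite fast)."""
    scale = duration_s / 900.0
    profile = tuple((t * scale, c) for t, c in sd.synthetic.DEFAULT_CET_PROFILE)
    return sd.SessionSpec(duration_s=duration_s, cet_profile=profile, **kwargs)


@pytest.fixture(scope="session")
def session600():
    """One 600 s synthetic session plus its features and labels."""
    sess = sd.simulate_session(scaled_spec(600.0, seed=1))
    feats, labels = sd.extract_session_features(sess.eeg, sess.ceff)
    return sess, feats, labels


@pytest.fixture(scope="session")
def cohort6():
    """Six 600 s synthetic subjects with per-subject features and labels."""
    sessions = sd.simulate_cohort(6, scaled_spec(600.0), seed=11)
    feats, labels = sd.cohort_features(sessions)
    return sessions, feats, labels


@pytest.fixture(scope="session")
def cohort10():
    """Ten 600 s synthetic subjects (for order-stability checks)."""
    sessions = sd.simulate_cohort(10, scaled_spec(600.0), seed=11)
    feats, labels = sd.cohort_features(sessions)
    return sessions, feats, labels


@pytest.fixture(scope="session")
def long_subject():
    """A single 1000 s subject (200 analysis windows) for capacity checks."""
    sess = sd.simulate_session(scaled_spec(1000.0, seed=3))
    feats, labels = sd.extract_session_features(sess.eeg, sess.ceff)
    return feats, labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
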