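import numpy as np
import pytest

import actimage as ai


@pytest.fixture(scope="session")
def templates():
    return ai.default_templates()


@pytest.fixture(scope="session")
def small_config():
    """One subject, one action, three repetitions."""
    return ai.ProtocolConfig(n_subjects=1, n_actions=1, n_repetitions=3, seed=7)


@pytest.fixture(scope="session")
def session_a6(templates, small_config):
    """A three-repetition body-punch session with ground truth."""
    return ai.generate_session(templates["A6"], small_config, "T1", seed=123)


@pytest.fixture(scope="session")
def segment_a6(session_a6):
    """The first ground-truth unit-action segment of the session."""
    profile, metas = session_a6
    m = metas[0]
    return profile.slice_frames(m.start_frame, m.end_frame)


@pytest.fixture
def tiny_profile():
    """3-frame, 1-joint profile with recognizable values."""
    rng = np.random.default_rng(5)
    values = rng.normal(0.0, 1.0, (3, 1, 6, 3))
    return ai.MotionProfile(values, sample_rate=240.0, joints=("right_hand",))
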