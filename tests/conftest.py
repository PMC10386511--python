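import numpy as np
import pytest

from groomkit import scenes


@pytest.fixture
def small_config():
    """Down-scaled scene for fast rendering in unit tests."""
    return scenes.SceneConfig(frame_size=(160, 120), subject_size=40,
                              walk_speed=3.0, seed=7)


@pytest.fixture
def default_config():
    return scenes.SceneConfig(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
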