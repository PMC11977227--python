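import numpy as np
import pytest

import pulseveil as pv


@pytest.fixture(scope="session")
def default_scene():
    """10-s default scene (72 bpm, sensor noise 0.5) shared across tests."""
    return pv.render_scene(pv.SceneConfig(duration=10.0, seed=1))


@pytest.fixture(scope="session")
def tiny_scene():
    """32×32 scene for exhaustive pixelwise checks."""
    return pv.render_scene(pv.SceneConfig(width=32, height=32, duration=2.0, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def random_video(rng):
    frames = rng.integers(0, 256, size=(8, 16, 16, 3), dtype=np.uint8)
    return pv.VideoSequence(frames, 25.0)
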