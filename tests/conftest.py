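import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import puncta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    """A deterministic small scene with a handful of bright spots."""
    cfg = puncta.SceneConfig(image_shape=(128, 128), rng_seed=7)
    scene, truth = puncta.simulate_scene(cfg)
    return cfg, scene, truth


@pytest.fixture
def full_mask():
    def _make(shape):
        return np.ones(shape, bool)

    return _make
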