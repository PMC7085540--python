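import numpy as np
import pytest
from scipy import ndimage

from activetrack import default_scene_config, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """One standard scene, shared read-only across tests."""
    cfg = default_scene_config(seed=1)
    frames, truth = generate_scene(cfg)
    return cfg, frames, truth


@pytest.fixture(scope="session")
def noise_texture():
    """A smooth noise texture large enough to cut translated crops from."""
    rng = np.random.default_rng(42)
    tex = ndimage.gaussian_filter(rng.uniform(size=(96, 96)), 1.5)
    return (tex - tex.min()) / (tex.max() - tex.min())
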