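import numpy as np
import pytest

from bivision import ScenarioConfig, make_scene


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down scenario: 32x128 working resolution (256x1024 full),
    8 targets, short warm-up.  Keeps full-pipeline tests fast while
    preserving the 8x decimation, blur and speed conventions."""
    return ScenarioConfig(decimated_shape=(32, 128), n_targets=8,
                          warmup_frames=120, eval_frames=40,
                          target_speed=29.0, background_speed=29.0)


@pytest.fixture(scope="session")
def small_scene(small_cfg):
    return make_scene(small_cfg, panorama_seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
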