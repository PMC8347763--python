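import numpy as np
import pytest

from fusionyield.io_grid import GridRaster
from fusionyield.synthetic import default_scene_config, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_raster(rng):
    vals = rng.uniform(0.0, 0.9, size=(4, 4)).astype(np.float32)
    return GridRaster(vals, origin_x=1000.0, origin_y=5000.0, pixel_size=30.0)


@pytest.fixture(scope="session")
def noise_free_scene():
    """Default three-plot scene, no noise: every stage has exact answers."""
    return generate_scene(default_scene_config(fine_shape=(64, 64)))


@pytest.fixture(scope="session")
def noise_free_scene_96():
    return generate_scene(default_scene_config())
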