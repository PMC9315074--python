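import numpy as np
import pytest

from octavd.raster_io import GrayImage
from octavd.synthetic import PhantomParams, default_battery, generate_phantom


@pytest.fixture(scope="session")
def battery14():
    """The 14-phantom default battery used for pipeline-level checks."""
    return default_battery(n=14, seed=42)


@pytest.fixture(scope="session")
def small_phantom():
    """One small phantom for fast compositional checks."""
    return generate_phantom(PhantomParams(size=(120, 120), vessel_count=5, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_image(rng):
    return GrayImage(rng.integers(0, 256, (40, 40), dtype=np.uint8))
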