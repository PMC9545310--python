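import numpy as np
import pytest

from ctvi.phantom import PhantomParams, generate_phantom
from ctvi.volumes import VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_triplet():
    """One deterministic 32³ phantom (ct, vent, mask, truth)."""
    return generate_phantom(PhantomParams(seed=5))


@pytest.fixture
def random_grid(rng):
    def make(shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0), positive=False):
        data = rng.random(shape)
        if positive:
            data = data + 0.1
        return VolumeGrid(data=data, spacing=spacing)

    return make
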