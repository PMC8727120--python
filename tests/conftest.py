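import numpy as np
import pytest

from fmrifuse.volumes import BrainMask, Volume3D, Volume4D


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_volume4d(rng):
    def make(shape=(6, 6, 6, 20), tr=2.0):
        return Volume4D(data=rng.standard_normal(shape) + 100.0, tr_seconds=tr)

    return make


@pytest.fixture
def full_mask():
    def make(shape=(6, 6, 6)):
        return BrainMask(data=np.ones(shape, dtype=bool))

    return make


@pytest.fixture
def random_map(rng):
    def make(shape=(8, 8, 8), spacing=(2.0, 2.0, 2.0)):
        return Volume3D(data=rng.standard_normal(shape), spacing_mm=spacing)

    return make
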