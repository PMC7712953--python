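import numpy as np
import pytest

from wmhkit import ImageVolume


@pytest.fixture
def affine2mm():
    return np.diag([2.0, 2.0, 2.0, 1.0])


@pytest.fixture
def make_volume(affine2mm):
    """Factory: ImageVolume on a 2 mm isotropic grid from an array."""

    def _make(data, affine=None):
        return ImageVolume(np.asarray(data), affine2mm if affine is None else affine)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
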