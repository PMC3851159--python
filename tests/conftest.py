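import numpy as np
import pytest

from rehopipe import BrainMask, Volume4D


AFFINE_3MM = np.diag([3.0, 3.0, 3.0, 1.0])


@pytest.fixture
def affine_3mm():
    return AFFINE_3MM.copy()


@pytest.fixture
def mask_10(affine_3mm):
    """Full 10x10x10 mask on a 3 mm isotropic grid."""
    return BrainMask(data=np.ones((10, 10, 10), dtype=bool), affine=affine_3mm)


@pytest.fixture
def noise_volume(mask_10):
    """i.i.d. Gaussian 10x10x10x20 volume, TR = 3 s, fixed seed."""
    rng = np.random.default_rng(7)
    return Volume4D(
        data=rng.standard_normal((10, 10, 10, 20)), affine=mask_10.affine, tr=3.0
    )
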