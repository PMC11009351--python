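import numpy as np
import pytest

from habitatpet.io_preproc import ImageVolume, TumorMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    """Random 8^3 CT-like volume at 1 mm."""
    data = rng.normal(-400, 300, (8, 8, 8))
    return ImageVolume(data, (1.0, 1.0, 1.0), modality="CT")


@pytest.fixture
def ball_mask():
    """Spherical mask of ~1000 voxels inside a 16^3 grid."""
    zz, yy, xx = np.mgrid[:16, :16, :16]
    mask = (zz - 7.5) ** 2 + (yy - 7.5) ** 2 + (xx - 7.5) ** 2 <= 6.2 ** 2
    return TumorMask(mask, (1.0, 1.0, 1.0))
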