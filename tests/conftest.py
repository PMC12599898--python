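import numpy as np
import pytest

from ctsim import AxialVolume


def make_volume(values_per_slice, positions, thickness=1.0, shape=(4, 4)):
    """Volume whose k-th slice is constant at values_per_slice[k]."""
    vox = np.stack([np.full(shape, v, dtype=np.float64) for v in values_per_slice])
    return AxialVolume(vox, np.asarray(positions, dtype=np.float64), thickness)


def make_ramp_volume(positions, slope=10.0, intercept=0.0, thickness=1.0, shape=(4, 4)):
    """Volume whose voxel values are affine in z: intercept + slope * z."""
    vals = [intercept + slope * z for z in positions]
    return make_volume(vals, positions, thickness, shape)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def random_volume(rng):
    n = 12
    return AxialVolume(
        rng.uniform(-1000.0, 1000.0, size=(n, 16, 16)),
        np.arange(n, dtype=np.float64),
        thickness=1.0,
    )
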