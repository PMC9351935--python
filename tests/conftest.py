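import numpy as np
import pytest

from naturakit.core import (
    MultiSubjectDataset,
    SubjectTimeSeries,
    VolumeGeometry,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_geometry():
    """4x4x4 grid with a 10-voxel mask."""
    dims = (4, 4, 4)
    mask = np.zeros(dims, bool)
    mask[np.unravel_index(np.arange(10), dims, order="F")] = True
    return VolumeGeometry(dims, (3.0, 3.0, 3.0), mask)


@pytest.fixture
def cube_geometry():
    """8x8x8 grid with a central 4x4x4 (64-voxel) mask."""
    dims = (8, 8, 8)
    mask = np.zeros(dims, bool)
    mask[2:6, 2:6, 2:6] = True
    return VolumeGeometry(dims, (3.0, 3.0, 3.0), mask)


def make_dataset(n=3, t=50, v=4, seed=0, shared=0.0, tr=1.0):
    """Independent-noise dataset, optionally with a common additive signal."""
    r = np.random.default_rng(seed)
    s = r.standard_normal((t, v)) * shared
    subs = [
        SubjectTimeSeries(s + r.standard_normal((t, v)), tr, f"s{i}")
        for i in range(n)
    ]
    return MultiSubjectDataset(subs)


@pytest.fixture
def noise_dataset():
    return make_dataset(n=4, t=60, v=5, seed=1)


@pytest.fixture
def shared_dataset():
    return make_dataset(n=4, t=200, v=5, seed=2, shared=1.0)
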