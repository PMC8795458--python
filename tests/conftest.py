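import numpy as np
import pytest

from neurograde import SyntheticSpec, VolumeSample
from neurograde.labels import CLASSES


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_spec():
    """The default phantom specification (60 volumes per class)."""
    return SyntheticSpec()


@pytest.fixture(scope="session")
def small_spec():
    """A light spec for I/O and manifest tests: 2 per class, 32-voxel cubes."""
    return SyntheticSpec(
        volume_shape=(32, 32, 32),
        n_per_class={c: 2 for c in CLASSES},
        lgg_radius_range=(4.0, 6.0),
        hgg_radius_range=(4.0, 6.0),
        seed=11,
    )


@pytest.fixture()
def random_volume(rng):
    vox = rng.random((20, 24, 16), dtype=np.float64) * 50 + 5
    return VolumeSample(voxels=vox, spacing_mm=(1.0, 1.5, 2.0), subject_id="rand")
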