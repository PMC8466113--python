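import numpy as np
import pytest

from focaldose.field_io import CurrentDensityField, VoxelGrid
from focaldose.synthetic_head import PhantomSpec


@pytest.fixture
def small_spec():
    """A coarse phantom that keeps unit tests fast: 40 mm sphere, 5 mm voxels, 12 parcels."""
    return PhantomSpec(radius=40.0, spacing=5.0, n_regions=12, seed=7)


@pytest.fixture
def unit_grid():
    """A 1 mm isotropic grid with identity affine."""
    def make(shape=(5, 5, 5)):
        return VoxelGrid(shape=shape, affine=np.eye(4))
    return make


@pytest.fixture
def scalar_field(unit_grid):
    """A scalar field on the unit grid with caller-supplied values."""
    def make(values, dose=1.0, mask=None):
        values = np.asarray(values, dtype=float)
        return CurrentDensityField(
            grid=unit_grid(values.shape[:3]), values=values, dose=dose, mask=mask
        )
    return make
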