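import numpy as np
import pytest

from gridspread.grids import LatticeGrid, Surface
from gridspread.pipeline import build_study_data
from gridspread.synthetic_data import make_landscape


@pytest.fixture(scope="session")
def small_landscape():
    """A compact landscape for SDM/richness/suitability tests."""
    return make_landscape(seed=7, n_rows=40, n_cols=36)


@pytest.fixture(scope="session")
def study_iid():
    """One full study replicate with i.i.d. response errors."""
    return build_study_data(seed=11, error_model="iid")


def make_surface(values, cell_size=10.0, land_fraction=None):
    values = np.asarray(values, dtype=float)
    grid = LatticeGrid(
        n_rows=values.shape[0],
        n_cols=values.shape[1],
        cell_size=cell_size,
        land_fraction=land_fraction,
    )
    return Surface(grid=grid, values=values)


@pytest.fixture
def surface_factory():
    return make_surface
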