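import numpy as np
import pytest

from rehofc.atlas import default_atlas
from rehofc.core import BoldSeries


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_series(data, tr_s=2.0, mask=None, voxel_size_mm=3.0):
    """Wrap a 4D array in a BoldSeries with a trivially valid geometry."""
    data = np.asarray(data, dtype=float)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldSeries(data=data, affine=np.diag([voxel_size_mm] * 3 + [1.0]),
                      tr_s=tr_s, voxel_size_mm=voxel_size_mm, mask=mask)


@pytest.fixture
def series_factory():
    return make_series
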