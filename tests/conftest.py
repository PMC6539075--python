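import numpy as np
import pytest

from npptrend.raster_core import RasterGrid, RasterStack
from npptrend.synthetic_data import ClimateSimConfig, simulate_climate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def climate_small():
    """One small correlated climate simulation shared across tests."""
    cfg = ClimateSimConfig(shape=(15, 15), seed=7, nodata_fraction=0.04)
    return simulate_climate(cfg)


def make_stack(cube: np.ndarray, times=None, variable="npp", **grid_kw) -> RasterStack:
    """Stack from an (n, rows, cols) float cube with NaN nodata."""
    n = cube.shape[0]
    times = list(range(2000, 2000 + n)) if times is None else times
    grids = [RasterGrid(cube[t], nodata=np.nan, **grid_kw) for t in range(n)]
    return RasterStack(grids, times, variable)
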