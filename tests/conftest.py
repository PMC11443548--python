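import numpy as np
import pandas as pd
import pytest

from seabloom import GeoField, GeoGrid


@pytest.fixture
def one_degree_grid():
    """1-degree grid spanning the southwest Indian Ocean study domain."""
    return GeoGrid(np.arange(-39.5, -15.0, 1.0), np.arange(30.5, 80.0, 1.0))


@pytest.fixture
def small_field():
    """Tiny 3-time field with a known mask for spatial-statistics tests."""
    grid = GeoGrid(np.array([-28.0, -27.0, -26.0]), np.array([50.0, 51.0, 52.0, 53.0]))
    times = pd.date_range("2019-11-01", periods=3, freq="D")
    values = np.arange(36, dtype=float).reshape(3, 3, 4)
    values[1, 0, 0] = np.nan
    return GeoField(grid=grid, times=times, values=values, units="mg m-3", name="chl")
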