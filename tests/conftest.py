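import datetime as dt

import numpy as np
import pytest

from kelpcanopy.dtm_classifier import KELP_ENDMEMBER, EndmemberLibrary
from kelpcanopy.geo_core import Grid, segment_coastline
from kelpcanopy.synthetic_data import WATER_ENDMEMBER, BedSpec, make_truth_scene


@pytest.fixture
def grid30():
    """A 60x60 Landsat-style grid, 30 m cells, origin at (0, 0)."""
    return Grid(60, 60, 0.0, 0.0, 30.0)


@pytest.fixture
def straight_coastline():
    """A vertical north-south coastline at x = 600 m, land to the west."""
    return segment_coastline(np.array([[600.0, 0.0], [600.0, -1800.0]]), 1000.0)


@pytest.fixture
def library():
    """Kelp endmember plus three slightly different water endmembers."""
    water = np.vstack([
        WATER_ENDMEMBER,
        WATER_ENDMEMBER + np.array([0.005, 0.004, 0.002, 0.001, 0.0, 0.0]),
        WATER_ENDMEMBER + np.array([-0.004, 0.002, 0.004, 0.002, 0.001, 0.0]),
    ])
    return EndmemberLibrary(kelp=KELP_ENDMEMBER, water=water)


@pytest.fixture
def simple_beds():
    return [
        BedSpec(x=1100.0, y=-500.0, rx=200.0, ry=150.0, peak=1.0, bed_id=0),
        BedSpec(x=1300.0, y=-1300.0, rx=150.0, ry=250.0, peak=0.7, bed_id=1),
    ]


@pytest.fixture
def noiseless_scene(grid30, straight_coastline, simple_beds):
    return make_truth_scene(grid30, straight_coastline, simple_beds,
                            noise_sd=0.0, seed=0,
                            acquired_at=dt.datetime(2015, 1, 15, 14, 0))
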