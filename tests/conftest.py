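import datetime as dt

import numpy as np
import pytest

from isotrack.grid import GridSpec, GridSurface
from isotrack.isoscape import Isoscape
from isotrack.tracks import Fix, Track


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return GridSpec(0.0, 50.0, 0.5, 20, 20)


def make_track(points, individual_id="bird1", species="puffin", winter="2007/08",
               start=dt.date(2007, 7, 1), step_days=1):
    """Build a Track from (lon, lat) pairs with evenly spaced dates."""
    fixes = [
        Fix(individual_id, start + dt.timedelta(days=i * step_days), lon, lat)
        for i, (lon, lat) in enumerate(points)
    ]
    return Track(individual_id, species, winter, fixes)


@pytest.fixture
def toy_isoscape():
    """3x3 isoscape with distinct, hand-checkable values."""
    c = GridSurface(0.0, 50.0, 1.0, np.array([
        [-20.0, -19.0, -18.0],
        [-19.5, -18.5, -17.5],
        [-19.0, -18.0, -17.0],
    ]))
    n = GridSurface(0.0, 50.0, 1.0, np.array([
        [8.0, 9.0, 10.0],
        [9.0, 10.0, 11.0],
        [10.0, 11.0, 12.0],
    ]))
    return Isoscape(d13C=c, d15N=n)
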