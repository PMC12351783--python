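import numpy as np
import pandas as pd
import pytest

from phenosurf.types import Fix, Track


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210301)


def make_track(times_lons_lats, individual="b1", species="SG", group="E"):
    fixes = [Fix(individual, pd.Timestamp(t), lon, lat)
             for t, lon, lat in times_lons_lats]
    return Track(individual, species, group, fixes)


@pytest.fixture
def simple_track():
    rows = [(f"2021-01-{d:02d}T{h:02d}:00:00", 100.0, 40.0)
            for d in range(1, 8) for h in (0, 8, 16)]
    return make_track(rows)
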