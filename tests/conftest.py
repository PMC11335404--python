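import numpy as np
import pandas as pd
import pytest

from abbi.strata import RegionSet


@pytest.fixture
def one_region():
    return RegionSet([("R1", -10.0, 50.0)])


@pytest.fixture
def two_regions():
    return RegionSet([("R1", -10.0, 50.0), ("R2", -10.0, 60.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(20130101)


def make_sets(n, trip_ids, declared, sampled, lat=-5.0, lon=55.0,
              date="2013-02-01", start_id=0):
    """A minimal purse-seine set table inside cell (-10, 50)."""
    return pd.DataFrame({
        "trip_id": trip_ids,
        "set_id": [f"S{start_id + i:05d}" for i in range(n)],
        "date": pd.Timestamp(date),
        "lat": lat,
        "lon": lon,
        "declared_catch": declared,
        "sampled": sampled,
    })


def make_samples(set_ids, species, proportions):
    return pd.DataFrame({"set_id": set_ids, "species": species,
                         "proportion": proportions})
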