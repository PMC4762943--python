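import warnings

import numpy as np
import pandas as pd
import pytest

from shelfshift import synthetic as syn
from shelfshift.survey import PeriodScheme

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def scheme():
    return PeriodScheme()


@pytest.fixture(scope="session")
def tracking_sim():
    """One seeded realization of the open-shelf velocity scenario
    (isotherm velocity 0.05 deg N/yr), shared across tests."""
    return syn.velocity_scenario(seed=101)


@pytest.fixture(scope="session")
def stationary_sim():
    """Same scenario with a time-invariant climate."""
    return syn.velocity_scenario(seed=102, warm_rate=0.0)


@pytest.fixture()
def tiny_survey():
    """Hand-written three-haul survey with two species."""
    hauls = pd.DataFrame({
        "haul_id": ["h1", "h2", "h3"],
        "year": [1970, 1985, 2005],
        "season": ["fall"] * 3,
        "region": ["south"] * 3,
        "latitude": [38.0, 38.5, 39.0],
        "longitude": [-73.0, -72.5, -72.0],
        "depth": [50.0, 80.0, 120.0],
        "sst": [16.0, 15.5, 15.0],
        "bt": [11.0, 10.5, 10.0],
        "stratum": ["s1", "s1", "s2"],
    })
    catches = pd.DataFrame({
        "haul_id": ["h1", "h2", "h2", "h3"],
        "species": ["cod", "cod", "hake", "hake"],
        "biomass": [3.0, 1.0, 2.0, 4.0],
    })
    return hauls, catches


def rng(seed=0):
    return np.random.default_rng(seed)
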