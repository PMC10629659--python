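import numpy as np
import pandas as pd
import pytest

from kbb_endoexo import (PopulationSpec, StudyConfig, TruthParams,
                         generate_monthly_climate, generate_topography,
                         simulate_counts)


@pytest.fixture(scope="session")
def tiny_config():
    """Two short-span populations; enough structure for lag chains."""
    return StudyConfig(
        populations=[PopulationSpec("PA", 3, 2000, 2008),
                     PopulationSpec("PB", 2, 2001, 2007)],
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    return simulate_counts(tiny_config, TruthParams(), seed=11)


@pytest.fixture(scope="session")
def default_config():
    """The full study-shaped configuration (5 populations, 48 sites)."""
    return StudyConfig(seed=5)


@pytest.fixture(scope="session")
def default_climate(default_config):
    return generate_monthly_climate(default_config, seed=5)


@pytest.fixture(scope="session")
def default_topo(default_config):
    return generate_topography(default_config, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def toy_climate():
    """One site, two years of hand-set monthly climate."""
    rows = []
    for year in (1999, 2000, 2001):
        for month in range(1, 13):
            mt = float(10 + month)
            rows.append(("S1", year, month, mt, mt + 5.0, mt - 5.0, 50.0 + month))
    return pd.DataFrame(rows, columns=["site", "year", "month", "MT", "AT", "IT", "PT"])
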