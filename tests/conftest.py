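import warnings

import numpy as np
import pandas as pd
import pytest

from avishift import (
    RasterGrid,
    WorldConfig,
    make_species_cohort,
    make_world,
    sample_occurrences,
)

# the sklearn penalty deprecation chatter is irrelevant to what we assert
warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")


@pytest.fixture(scope="session")
def small_config() -> WorldConfig:
    return WorldConfig(n_rows=30, n_cols=40, seed=11)


@pytest.fixture(scope="session")
def small_world(small_config):
    return make_world(small_config)


@pytest.fixture(scope="session")
def cohort(small_config, small_world):
    return make_species_cohort(small_config, small_world["climate_current"],
                               n_species=5, seed=21)


@pytest.fixture(scope="session")
def occurrences(cohort, small_world) -> pd.DataFrame:
    cur = small_world["climate_current"]
    return pd.concat(
        [sample_occurrences(t, cur, 150, seed=100 + i)
         for i, t in enumerate(cohort)],
        ignore_index=True,
    )


@pytest.fixture()
def unit_grid():
    """Tiny 4x5 single-band grid with a simple georeference."""
    vals = np.arange(20, dtype=float).reshape(4, 5)
    return RasterGrid(vals, lon_west=10.0, lat_north=50.0, cell_size=0.5)
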