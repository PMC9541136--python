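import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from robitt.core import PeriodSpec, TargetPopulation


@pytest.fixture
def unit_pop():
    """Small target population on a 10x10-degree box, two decades."""
    return TargetPopulation(
        geo_extent=box(0, 0, 10, 10),
        temporal_extent=(2000, 2019),
        taxa=("Amazilia amabilis", "Colibri coruscans"),
        spatial_resolution=1.0,
        temporal_resolution=10,
        grid_origin=(0.0, 0.0),
    )


@pytest.fixture
def decadal_periods():
    return PeriodSpec(1950, 2019, 10)


def make_records(rows):
    """Occurrence frame from (taxon, lon, lat, year[, count, unc, source]) tuples."""
    full = [tuple(r) + (None,) * (7 - len(r)) for r in rows]
    return pd.DataFrame(
        full, columns=["taxon", "lon", "lat", "year", "count", "coord_uncertainty_m", "source"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
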