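import numpy as np
import pytest

from isoassign import (
    GeoGrid,
    GridGeometry,
    SyntheticCohortConfig,
    SyntheticWorldConfig,
    make_synthetic_isoscape,
    simulate_known_origin,
)


@pytest.fixture
def small_geometry() -> GridGeometry:
    return GridGeometry(n_rows=3, n_cols=3, west=-100.0, north=50.0,
                        cell_width=1.0, cell_height=1.0)


@pytest.fixture
def small_grid(small_geometry) -> GeoGrid:
    values = np.arange(9, dtype=float).reshape(3, 3)
    values[1, 1] = np.nan
    return GeoGrid(geometry=small_geometry, values=values, units="permil")


@pytest.fixture
def world_config() -> SyntheticWorldConfig:
    return SyntheticWorldConfig(
        geometry=GridGeometry(n_rows=60, n_cols=60, west=-120.0, north=60.0,
                              cell_width=0.5, cell_height=0.5),
        gradient=(-160.0, -20.0),
        spatial_noise_sd=5.0,
        smoothing_radius=1,
        isoscape_sd_level=3.0,
        seed=11,
    )


@pytest.fixture
def synthetic_world(world_config):
    return make_synthetic_isoscape(world_config)


@pytest.fixture
def synthetic_records(synthetic_world):
    isoscape, _ = synthetic_world
    cohort = SyntheticCohortConfig(
        n_sites=50, birds_per_site=5, true_intercept=-60.0, true_slope=0.8,
        residual_sd=12.0, seed=21,
    )
    return simulate_known_origin(cohort, isoscape)
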