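"""Probability-of-origin surfaces and odds-ratio origin regions.

Each individual's surface is a normalized normal density over the working
grid: cell mean = predicted feather value, cell SD = the combined error
``sigma_c = sqrt(sd_resid^2 + (slope * sigma_isoscape)^2)``.  The 2:1
odds-ratio region is the smallest set of highest-probability cells whose
cumulative probability reaches 2/3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationModel
from .geodesy import haversine_km, sphere_centroid
from .grid import (
    AlignmentError,
    GeoGrid,
    GridError,
    GridGeometry,
    RegionMask,
    UncertaintySurface,
)

__all__ = [
    "ProbabilitySurface",
    "OriginRegion",
    "CohortAssignment",
    "combined_sigma",
    "probability_surface",
    "odds_region",
    "stack_regions",
    "region_centroid",
    "region_centroid_distance",
    "assign_cohort",
    "parse_odds",
]

#: Slack used when accumulating float probabilities against the odds
#: threshold; far below any meaningful probability mass.
_MASS_EPS = 1e-12


def parse_odds(odds: str | float) -> float:
    """Convert an odds-ratio spec ("2:1" or a fraction in (0, 1]) to the
    cumulative-probability threshold (2:1 -> 2/3)."""
    if isinstance(odds, str) and ":" in odds:
        num, den = odds.split(":", 1)
        a, b = float(num), float(den)
        if a <= 0 or b <= 0:
            raise ValueError(f"invalid odds ratio {odds!r}")
        return a / (a + b)
    value = float(odds)
    if not (0.0 < value <= 1.0):
        raise ValueError(f"odds fraction must lie in (0, 1], got {value}")
    return value


@dataclass
class ProbabilitySurface:
    """Normalized per-individual probability-of-origin raster."""

    grid: GeoGrid
    individual_id: str = ""

    def __post_init__(self) -> None:
        vals = self.grid.values
        valid = vals[~np.isnan(vals)]
        if valid.size == 0:
            raise GridError("probability surface has an empty domain")
        if np.any(valid < 0):
            raise GridError("probability surface has negative values")
        total = float(valid.sum())
        if abs(total - 1.0) > 1e-9:
            raise GridError(f"probability surface sums to {total}, not 1")

    @property
    def geometry(self) -> GridGeometry:
        return self.grid.geometry


@dataclass
class OriginRegion:
    """Binary region of likely origin extracted at a given odds fraction."""

    included: np.ndarray
    geometry: GridGeometry
    odds_fraction: float
    achieved_mass: float
    n_domain_cells: int
    individual_id: str = ""

    def __post_init__(self) -> None:
        self.included = np.asarray(self.included, dtype=bool)
        if self.included.shape != self.geometry.shape:
            raise GridError("region shape does not match its geometry")
        if not (0.0 < self.odds_fraction <= 1.0):
            raise ValueError("odds_fraction must lie in (0, 1]")
        if self.achieved_mass < self.odds_fraction - 1e-9:
            raise ValueError("achieved_mass below the odds fraction")

    @property
    def cell_count(self) -> int:
        return int(self.included.sum())

    @property
    def precision(self) -> float:
        """Included cells over total non-nodata cells of the working grid."""
        return self.cell_count / self.n_domain_cells

    def indicator_grid(self) -> GeoGrid:
        return GeoGrid(
            geometry=self.geometry,
            values=self.included.astype(float),
            units="count",
            name=f"region_{self.individual_id}" if self.individual_id else "region",
        )


def combined_sigma(
    model: CalibrationModel,
    unc: UncertaintySurface | None,
    geometry: GridGeometry | None = None,
    *,
    scale_by_slope: bool = True,
) -> GeoGrid:
    """Per-cell expected SD combining calibration and isoscape error.

    ``sigma_c = sqrt(sd_resid^2 + (slope * sigma_isoscape)^2)``; with no
    uncertainty surface the result is the constant ``sd_resid`` (the
    placeholder-grid convention for isoscapes without error estimates).
    ``scale_by_slope=False`` combines the raw isoscape SD instead.
    """
    if unc is None:
        if geometry is None:
            raise ValueError("geometry is required when unc is None")
        values = np.full(geometry.shape, model.sd_resid)
        return GeoGrid(geometry=geometry, values=values, units="permil",
                       name="sigma_c")
    if geometry is not None and not unc.geometry.aligned(geometry):
        raise AlignmentError("uncertainty surface not aligned with working geometry")
    iso_sd = unc.grid.values
    if np.any(iso_sd[~np.isnan(iso_sd)] < 0):
        raise GridError("negative isoscape uncertainty values")
    factor = abs(model.slope) if scale_by_slope else 1.0
    values = np.sqrt(model.sd_resid**2 + (factor * iso_sd) ** 2)
    return GeoGrid(geometry=unc.geometry, values=values, units="permil",
                   name="sigma_c")


def probability_surface(
    d2h_f: float,
    feather_grid: GeoGrid,
    sigma_grid: GeoGrid,
    mask: RegionMask | None = None,
    individual_id: str = "",
) -> ProbabilitySurface:
    """Normalized normal-density surface for one individual.

    The normalization domain is every cell that is non-nodata in both grids
    and inside the mask (when given); densities are divided by the domain
    sum so the surface is a probability of origin.
    """
    if not feather_grid.geometry.aligned(sigma_grid.geometry):
        raise AlignmentError("feather and sigma grids are not aligned")
    mu = feather_grid.values
    sigma = sigma_grid.values
    domain = ~np.isnan(mu) & ~np.isnan(sigma)
    if mask is not None:
        domain &= mask.rasterize(feather_grid.geometry)
    if not domain.any():
        raise GridError(
            f"empty normalization domain for individual {individual_id or '?'}"
        )
    if np.any(sigma[domain] <= 0):
        raise GridError("sigma must be > 0 on every domain cell")
    dens = np.full(mu.shape, np.nan)
    s = sigma[domain]
    z = (d2h_f - mu[domain]) / s
    dens[domain] = np.exp(-0.5 * z * z) / (s * math.sqrt(2.0 * math.pi))
    total = dens[domain].sum()
    if total <= 0:
        raise GridError("probability surface has zero total density")
    dens[domain] /= total
    grid = GeoGrid(
        geometry=feather_grid.geometry, values=dens, units="probability",
        name=f"p_origin_{individual_id}" if individual_id else "p_origin",
    )
    return ProbabilitySurface(grid=grid, individual_id=individual_id)


def odds_region(
    surface: ProbabilitySurface, odds_fraction: float = 2.0 / 3.0
) -> OriginRegion:
    """Minimal prefix of cells, sorted by probability descending (ties broken
    by row-major index), whose cumulative probability reaches the fraction."""
    if not (0.0 < odds_fraction <= 1.0):
        raise ValueError(f"odds_fraction must lie in (0, 1], got {odds_fraction}")
    p = surface.grid.values
    flat = p.ravel()
    valid = ~np.isnan(flat)
    # Stable argsort keeps ties in row-major order; invalid cells sort last.
    keyed = np.where(valid, flat, -1.0)
    order = np.argsort(-keyed, kind="stable")
    n_valid = int(valid.sum())
    ordered = order[:n_valid]
    cum = np.cumsum(flat[ordered])
    if odds_fraction >= 1.0:
        # Exactly total mass requested: every domain cell is included.
        k = n_valid
    else:
        reached = np.nonzero(cum >= odds_fraction - _MASS_EPS)[0]
        k = int(reached[0]) + 1 if reached.size else n_valid
    included = np.zeros(flat.shape, dtype=bool)
    included[ordered[:k]] = True
    return OriginRegion(
        included=included.reshape(p.shape),
        geometry=surface.geometry,
        odds_fraction=odds_fraction,
        achieved_mass=float(cum[k - 1]),
        n_domain_cells=n_valid,
        individual_id=surface.individual_id,
    )


def stack_regions(regions: Sequence[OriginRegion]) -> GeoGrid:
    """Integer count grid: number of regions including each cell."""
    if not regions:
        raise GridError("stack_regions requires at least one region")
    geometry = regions[0].geometry
    counts = np.zeros(geometry.shape, dtype=float)
    for region in regions:
        if region.geometry != geometry:
            raise AlignmentError("regions have mismatching geometries")
        counts += region.included
    return GeoGrid(geometry=geometry, values=counts, units="count",
                   name="region_stack")


def region_centroid(region: OriginRegion) -> tuple[float, float]:
    """Unweighted mean position (lon, lat) of included cell centers,
    averaged on the unit sphere."""
    rows, cols = np.nonzero(region.included)
    if rows.size == 0:
        raise GridError("cannot take the centroid of an empty region")
    geom = region.geometry
    lons = geom.west + (cols + 0.5) * geom.cell_width
    lats = geom.north - (rows + 0.5) * geom.cell_height
    return sphere_centroid(lons, lats)


def region_centroid_distance(region_a: OriginRegion, region_b: OriginRegion) -> float:
    """Great-circle distance (km) between the two region centroids."""
    lon_a, lat_a = region_centroid(region_a)
    lon_b, lat_b = region_centroid(region_b)
    return float(haversine_km(lon_a, lat_a, lon_b, lat_b))


@dataclass
class CohortAssignment:
    """Per-record origin regions plus their stacked count grid."""

    regions: list[OriginRegion]
    stack: GeoGrid
    summary: pd.DataFrame


def assign_cohort(
    d2h_f_values: Sequence[float],
    feather_grid: GeoGrid,
    sigma_grid: GeoGrid,
    range_mask: RegionMask | None = None,
    odds_fraction: float = 2.0 / 3.0,
    ids: Sequence[str] | None = None,
) -> CohortAssignment:
    """Run probability_surface -> odds_region for every individual.

    The range mask (species breeding range, continent) is applied before
    normalization.  Returns the regions, their stack, and a per-record
    summary (region cell count, achieved mass, precision).
    """
    if ids is None:
        ids = [f"ind-{i:04d}" for i in range(len(d2h_f_values))]
    if len(ids) != len(d2h_f_values):
        raise ValueError("ids and d2h_f_values lengths differ")
    regions = []
    rows = []
    for ind_id, value in zip(ids, d2h_f_values):
        surface = probability_surface(
            float(value), feather_grid, sigma_grid, mask=range_mask,
            individual_id=str(ind_id),
        )
        region = odds_region(surface, odds_fraction)
        regions.append(region)
        rows.append(
            {
                "id": str(ind_id),
                "d2h_f": float(value),
                "region_cells": region.cell_count,
                "achieved_mass": region.achieved_mass,
                "precision": region.precision,
            }
        )
    return CohortAssignment(
        regions=regions,
        stack=stack_regions(regions),
        summary=pd.DataFrame(rows),
    )
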