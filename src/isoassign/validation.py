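"""Repeated split-half cross-validation of a calibration/isoscape pairing.

Each iteration randomly halves the records, fits the calibration on one
half, converts the isoscape to feather space, assigns every validation bird
with a normal-density surface and extracts its odds-ratio region, then
scores:

* accuracy — proportion of validation birds whose sampling cell falls
  inside their region;
* precision — region cells over total non-nodata working cells, averaged
  over all validation birds;
* minimum distance — great-circle km from the sampling point to the nearest
  region cell, averaged over inaccurately assigned birds only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assignment import OriginRegion, combined_sigma, odds_region, probability_surface
from .calibration import (
    CalibrationModel,
    CalibrationPair,
    KnownOriginRecord,
    fit_calibration,
    predict_feather_isoscape,
)
from .geodesy import haversine_km
from .grid import (
    GeoGrid,
    GridError,
    OutOfBoundsError,
    RegionMask,
    UncertaintySurface,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationIteration",
    "split_half",
    "region_metrics",
    "min_distance_km",
    "cross_validate",
    "iterations_to_frame",
    "grand_summary",
]

#: Offset applied when redrawing an iteration whose calibration half is
#: degenerate; keeps replacement seeds disjoint from the base sequence.
_REDRAW_OFFSET = 10_000_019


@dataclass
class ValidationIteration:
    """Scores and fitted calibration for one split-half iteration."""

    iteration: int
    seed: int
    n_cal: int
    n_val: int
    accuracy: float
    mean_precision: float
    mean_min_distance_km: float  # NaN when every bird was accurate
    calibration: CalibrationModel

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")
        if not (0.0 <= self.mean_precision <= 1.0):
            raise ValueError("mean_precision must lie in [0, 1]")
        if not math.isnan(self.mean_min_distance_km) and self.mean_min_distance_km < 0:
            raise ValueError("mean_min_distance_km must be >= 0")


def split_half(
    records: Sequence[KnownOriginRecord], seed: int
) -> tuple[list[KnownOriginRecord], list[KnownOriginRecord]]:
    """Random disjoint exhaustive split; the calibration half gets
    ceil(n/2) records. Deterministic given the seed."""
    n = len(records)
    if n < 6:
        raise ValueError(f"split_half requires >= 6 records, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    n_cal = math.ceil(n / 2)
    cal = [records[i] for i in perm[:n_cal]]
    val = [records[i] for i in perm[n_cal:]]
    return cal, val


def region_metrics(
    region: OriginRegion, lon: float, lat: float
) -> tuple[bool, float]:
    """(accurate, precision) for one bird.

    accurate: the region includes the cell owning the sampling point;
    precision: included cells over total non-nodata cells of the masked
    working grid.
    """
    row, col = region.geometry.index_of(lon, lat)
    accurate = bool(region.included[row, col])
    return accurate, region.precision


def min_distance_km(region: OriginRegion, lon: float, lat: float) -> float:
    """Minimum great-circle distance from the point to any included cell
    center (0 when the point's own cell is included)."""
    rows, cols = np.nonzero(region.included)
    if rows.size == 0:
        raise GridError("min_distance_km on an empty region")
    geom = region.geometry
    cell_lons = geom.west + (cols + 0.5) * geom.cell_width
    cell_lats = geom.north - (rows + 0.5) * geom.cell_height
    return float(np.min(haversine_km(lon, lat, cell_lons, cell_lats)))


def _fit_on(records: Sequence[KnownOriginRecord], d2h_p: Mapping[str, float],
            isoscape: str) -> CalibrationModel:
    pairs = [CalibrationPair(r, d2h_p[r.id]) for r in records]
    return fit_calibration(pairs, dataset="cv", isoscape=isoscape)


def cross_validate(
    records: Sequence[KnownOriginRecord],
    mean_grid: GeoGrid,
    unc_grid: UncertaintySurface | None = None,
    iterations: int = 25,
    odds_fraction: float = 2.0 / 3.0,
    base_seed: int = 0,
    continent_masks: Mapping[str, RegionMask] | None = None,
    scale_sigma_by_slope: bool = True,
    min_distance_all_birds: bool = False,
) -> list[ValidationIteration]:
    """Repeated split-half cross-validation.

    Records must be pre-filtered (outliers and excluded sites removed) and
    the grids prepared (masked to the working continents).  Records whose
    sampling point misses the grid are dropped up front with a logged id;
    iterations whose calibration half is degenerate are redrawn with a
    logged replacement seed, keeping the iteration count fixed.

    ``continent_masks`` optionally limits each bird's normalization domain
    to the mask for its ``continent`` label.  With the default
    ``min_distance_all_birds=False`` only inaccurate birds enter the
    minimum-distance mean (each contribution > 0); the all-birds variant
    includes zeros for accurate birds.
    """
    usable: list[KnownOriginRecord] = []
    d2h_p: dict[str, float] = {}
    for rec in records:
        try:
            value = float(
                mean_grid.values[mean_grid.geometry.index_of(rec.lon, rec.lat)]
            )
        except OutOfBoundsError:
            value = float("nan")
        if np.isnan(value):
            logger.info("dropping record %s: no overlap with the working grid",
                        rec.id)
            continue
        usable.append(rec)
        d2h_p[rec.id] = value
    if len(usable) < 6:
        raise ValueError("too few usable records for cross-validation")

    masks = dict(continent_masks) if continent_masks else {}
    results: list[ValidationIteration] = []
    for i in range(iterations):
        seed = base_seed + i
        attempt = 0
        while True:
            cal, val = split_half(usable, seed)
            x = np.array([d2h_p[r.id] for r in cal])
            if np.ptp(x) > 0:
                break
            attempt += 1
            new_seed = base_seed + i + attempt * _REDRAW_OFFSET
            logger.warning(
                "iteration %d: degenerate calibration half with seed %d; "
                "redrawing with seed %d", i, seed, new_seed,
            )
            seed = new_seed
        model = _fit_on(cal, d2h_p, mean_grid.name)
        feather = predict_feather_isoscape(mean_grid, model)
        sigma = combined_sigma(
            model, unc_grid, feather.geometry, scale_by_slope=scale_sigma_by_slope
        )

        n_acc = 0
        precisions: list[float] = []
        distances: list[float] = []
        n_scored = 0
        for rec in val:
            mask = masks.get(rec.continent)
            surface = probability_surface(
                rec.d2h_f, feather, sigma, mask=mask, individual_id=rec.id
            )
            region = odds_region(surface, odds_fraction)
            try:
                accurate, precision = region_metrics(region, rec.lon, rec.lat)
            except OutOfBoundsError:
                logger.info("iteration %d: skipping record %s (sampling point "
                            "outside masked grid)", i, rec.id)
                continue
            n_scored += 1
            n_acc += accurate
            precisions.append(precision)
            if not accurate:
                distances.append(min_distance_km(region, rec.lon, rec.lat))
            elif min_distance_all_birds:
                distances.append(0.0)
        if n_scored == 0:
            raise GridError(f"iteration {i}: no scorable validation birds")
        results.append(
            ValidationIteration(
                iteration=i,
                seed=seed,
                n_cal=len(cal),
                n_val=len(val),
                accuracy=n_acc / n_scored,
                mean_precision=float(np.mean(precisions)),
                mean_min_distance_km=(
                    float(np.mean(distances)) if distances else float("nan")
                ),
                calibration=model,
            )
        )
    return results


def iterations_to_frame(iterations: Sequence[ValidationIteration]) -> pd.DataFrame:
    """One row per iteration, matching the validation output CSV schema."""
    return pd.DataFrame(
        [
            {
                "iteration": it.iteration,
                "seed": it.seed,
                "n_cal": it.n_cal,
                "n_val": it.n_val,
                "accuracy": it.accuracy,
                "mean_precision": it.mean_precision,
                "mean_min_distance_km": it.mean_min_distance_km,
                "intercept": it.calibration.intercept,
                "slope": it.calibration.slope,
                "sd_resid": it.calibration.sd_resid,
                "r2_adj": it.calibration.r2_adj,
            }
            for it in iterations
        ]
    )


def grand_summary(iterations: Sequence[ValidationIteration]) -> dict[str, float]:
    """Mean and SD across iterations of each score."""
    frame = iterations_to_frame(iterations)
    out: dict[str, float] = {"n_iterations": float(len(iterations))}
    for col in ("accuracy", "mean_precision", "mean_min_distance_km"):
        series = frame[col].dropna()
        out[f"{col}_mean"] = float(series.mean()) if len(series) else float("nan")
        out[f"{col}_sd"] = (
            float(series.std(ddof=1)) if len(series) > 1 else float("nan")
        )
    return out
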