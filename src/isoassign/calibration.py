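"""Known-origin records, site-wise outlier fences, and the linear calibration.

The calibration maps precipitation-space d2H (``d2h_p``, extracted from an
isoscape at each sampling location) to tissue-space d2H (``d2h_f``) via
ordinary least squares.  Records are screened once, before fitting, with a
per-site 1.5*IQR fence on ``d2h_f`` (linear-interpolation sample quantiles);
manually excluded sites are handled by an exclusion list, not the fence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import GeoGrid, OutOfBoundsError, extract_at_point

logger = logging.getLogger(__name__)

__all__ = [
    "KnownOriginRecord",
    "CalibrationPair",
    "CalibrationModel",
    "GUILDS",
    "AGE_CLASSES",
    "CONTINENTS",
    "flag_site_outliers",
    "nonoverlap_ids",
    "pair_with_isoscape",
    "build_pairs",
    "fit_calibration",
    "predict_feather_isoscape",
    "read_records_csv",
    "write_records_csv",
    "records_to_frame",
]

GUILDS = ("dabbler", "diver")
AGE_CLASSES = ("HY", "adult", "unknown")
CONTINENTS = ("NorthAmerica", "Europe")

RECORDS_CSV_COLUMNS = (
    "id", "dataset", "species", "guild", "age", "site_id",
    "lon", "lat", "d2h_f", "truth_d2h_p", "is_outlier",
)

EXCLUDE_OUTLIER = "outlier"
EXCLUDE_SITE = "site-excluded"
EXCLUDE_NO_OVERLAP = "no-isoscape-overlap"


@dataclass
class KnownOriginRecord:
    """One known-origin bird: location, site, guild, and feather d2H."""

    id: str
    site_id: str
    lon: float
    lat: float
    d2h_f: float
    dataset: str = "unknown"
    species: str = "unknown"
    guild: str = "dabbler"
    age_class: str = "unknown"
    continent: str = "NorthAmerica"
    # Generator bookkeeping (synthetic cohorts only).
    truth_d2h_p: float | None = None
    is_outlier: bool = False

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"record {self.id}: lat {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon < 180.0):
            raise ValueError(f"record {self.id}: lon {self.lon} outside [-180, 180)")
        if not np.isfinite(self.d2h_f):
            raise ValueError(f"record {self.id}: d2h_f is not finite")
        if self.guild not in GUILDS:
            raise ValueError(f"record {self.id}: unknown guild {self.guild!r}")
        if self.continent not in CONTINENTS:
            raise ValueError(f"record {self.id}: unknown continent {self.continent!r}")


@dataclass
class CalibrationPair:
    """A record paired with its extracted isoscape value, or an exclusion."""

    record: KnownOriginRecord
    d2h_p: float
    excluded: bool = False
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.excluded and self.reason not in (
            EXCLUDE_OUTLIER, EXCLUDE_SITE, EXCLUDE_NO_OVERLAP
        ):
            raise ValueError(f"excluded pair requires exactly one known reason, "
                             f"got {self.reason!r}")
        if not self.excluded and self.reason is not None:
            raise ValueError("non-excluded pair must not carry a reason")


@dataclass
class CalibrationModel:
    """OLS calibration d2h_f = intercept + slope * d2h_p for one pairing."""

    intercept: float
    slope: float
    sd_resid: float
    r2_adj: float
    n: int
    dataset: str = ""
    isoscape: str = ""

    def __post_init__(self) -> None:
        if self.sd_resid < 0:
            raise ValueError("sd_resid must be non-negative")
        if self.n < 3:
            raise ValueError(f"calibration requires n >= 3, got {self.n}")
        if self.r2_adj > 1 + 1e-12:
            raise ValueError("r2_adj cannot exceed 1")

    def predict(self, d2h_p):
        return self.intercept + self.slope * np.asarray(d2h_p, dtype=float)


def flag_site_outliers(
    records: Sequence[KnownOriginRecord],
    exclusion_sites: Iterable[str] = (),
) -> list[str | None]:
    """Single-pass per-site Tukey fence on d2h_f.

    Returns one reason per record: ``"outlier"`` for values outside
    ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]`` of their site, ``"site-excluded"`` for
    records at sites on the exclusion list, else ``None``.  Quartiles use
    linear interpolation between order statistics; small sites (1-3 records)
    get fences from their own quantiles, so a single-valued site flags
    nothing.
    """
    excluded = set(exclusion_sites)
    by_site: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        by_site.setdefault(rec.site_id, []).append(i)
    reasons: list[str | None] = [None] * len(records)
    for site, idx in by_site.items():
        if site in excluded:
            for i in idx:
                reasons[i] = EXCLUDE_SITE
            continue
        vals = np.array([records[i].d2h_f for i in idx])
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        for i, v in zip(idx, vals):
            if v < lo or v > hi:
                reasons[i] = EXCLUDE_OUTLIER
    return reasons


def nonoverlap_ids(
    records: Sequence[KnownOriginRecord],
    grids: Sequence[GeoGrid],
) -> set[str]:
    """Ids of records falling on nodata or out-of-bounds cells of ANY grid.

    Non-overlap on any configured isoscape removes the record from all
    pairings (global exclusion).
    """
    bad: set[str] = set()
    for grid in grids:
        for rec in records:
            try:
                value = extract_at_point(grid, rec.lon, rec.lat)
            except OutOfBoundsError:
                bad.add(rec.id)
                continue
            if np.isnan(value):
                bad.add(rec.id)
    if bad:
        logger.info("excluded %d record(s) without isoscape overlap: %s",
                    len(bad), sorted(bad))
    return bad


def pair_with_isoscape(
    records: Sequence[KnownOriginRecord],
    grid: GeoGrid,
    *,
    outlier_reasons: Sequence[str | None] | None = None,
    excluded_ids: Iterable[str] = (),
) -> list[CalibrationPair]:
    """Pair records with isoscape values extracted at their locations.

    ``excluded_ids`` (typically from :func:`nonoverlap_ids` across all
    configured isoscapes) take priority, then site/outlier reasons from
    ``outlier_reasons``.
    """
    excluded = set(excluded_ids)
    pairs: list[CalibrationPair] = []
    for i, rec in enumerate(records):
        try:
            d2h_p = extract_at_point(grid, rec.lon, rec.lat)
        except OutOfBoundsError:
            d2h_p = float("nan")
        if rec.id in excluded or np.isnan(d2h_p):
            pairs.append(CalibrationPair(rec, d2h_p, True, EXCLUDE_NO_OVERLAP))
            continue
        reason = outlier_reasons[i] if outlier_reasons is not None else None
        if reason is not None:
            pairs.append(CalibrationPair(rec, d2h_p, True, reason))
        else:
            pairs.append(CalibrationPair(rec, d2h_p))
    n_excluded = sum(p.excluded for p in pairs)
    if n_excluded:
        logger.info("pair_with_isoscape: %d of %d records excluded",
                    n_excluded, len(records))
    return pairs


def build_pairs(
    records: Sequence[KnownOriginRecord],
    grid: GeoGrid,
    *,
    exclusion_sites: Iterable[str] = (),
    extra_grids: Sequence[GeoGrid] = (),
) -> list[CalibrationPair]:
    """Full screening pipeline: global non-overlap exclusion across all
    configured grids, then the site fence pass, then pairing."""
    bad_ids = nonoverlap_ids(records, [grid, *extra_grids])
    surviving = [r for r in records if r.id not in bad_ids]
    reasons = flag_site_outliers(surviving, exclusion_sites)
    reason_by_id = {r.id: reason for r, reason in zip(surviving, reasons)}
    all_reasons = [reason_by_id.get(r.id) for r in records]
    return pair_with_isoscape(
        records, grid, outlier_reasons=all_reasons, excluded_ids=bad_ids
    )


def fit_calibration(
    pairs: Sequence[CalibrationPair],
    dataset: str = "",
    isoscape: str = "",
) -> CalibrationModel:
    """Ordinary least squares of d2h_f on d2h_p over non-excluded pairs.

    ``sd_resid`` is the sample standard deviation of residuals (divisor
    n - 1); ``r2_adj = 1 - (1 - r2) * (n - 1) / (n - 2)``.
    """
    used = [p for p in pairs if not p.excluded]
    if len(used) < 3:
        raise ValueError(f"calibration requires >= 3 usable pairs, got {len(used)}")
    x = np.array([p.d2h_p for p in used])
    y = np.array([p.record.d2h_f for p in used])
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("degenerate predictor: all d2h_p values identical")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sd_resid = float(np.std(resid, ddof=1))
    syy = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if syy == 0 else 1.0 - float(np.sum(resid**2)) / syy
    n = len(used)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return CalibrationModel(
        intercept=intercept, slope=slope, sd_resid=sd_resid,
        r2_adj=r2_adj, n=n, dataset=dataset, isoscape=isoscape,
    )


def predict_feather_isoscape(grid: GeoGrid, model: CalibrationModel) -> GeoGrid:
    """Cellwise ``intercept + slope * value``; nodata preserved."""
    values = model.intercept + model.slope * grid.values
    return GeoGrid(
        geometry=grid.geometry,
        values=values,
        units=grid.units,
        name=f"{grid.name}_feather" if grid.name else "feather",
        nodata=grid.nodata,
    )


# ---------------------------------------------------------------------------
# Records CSV
# ---------------------------------------------------------------------------


def records_to_frame(records: Sequence[KnownOriginRecord]) -> pd.DataFrame:
    rows = [
        {
            "id": r.id,
            "dataset": r.dataset,
            "species": r.species,
            "guild": r.guild,
            "age": r.age_class,
            "site_id": r.site_id,
            "lon": r.lon,
            "lat": r.lat,
            "d2h_f": r.d2h_f,
            "truth_d2h_p": r.truth_d2h_p if r.truth_d2h_p is not None else "",
            "is_outlier": int(r.is_outlier),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(RECORDS_CSV_COLUMNS))


def write_records_csv(records: Sequence[KnownOriginRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[KnownOriginRecord]:
    """Read records, reporting schema violations with line numbers."""
    df = pd.read_csv(path, dtype={"id": str, "site_id": str})
    required = ("id", "site_id", "lon", "lat", "d2h_f")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: records CSV is missing column {col!r}")
    records = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            truth = row.get("truth_d2h_p")
            truth = None if truth is None or pd.isna(truth) or truth == "" \
                else float(truth)
            records.append(
                KnownOriginRecord(
                    id=str(row["id"]),
                    site_id=str(row["site_id"]),
                    lon=float(row["lon"]),
                    lat=float(row["lat"]),
                    d2h_f=float(row["d2h_f"]),
                    dataset=str(row.get("dataset", "unknown")),
                    species=str(row.get("species", "unknown")),
                    guild=str(row.get("guild", "dabbler")),
                    age_class=str(row.get("age", "unknown")),
                    continent=str(row.get("continent", "NorthAmerica")),
                    truth_d2h_p=truth,
                    is_outlier=bool(int(row["is_outlier"]))
                    if "is_outlier" in df.columns and not pd.isna(row["is_outlier"])
                    else False,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from exc
    return records
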