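"""Lat/lon raster data model and I/O.

Grids are north-up rectangular rasters in geographic coordinates (WGS84
lon/lat), with values located at cell centers.  Nodata is represented
internally as NaN; files carry an explicit nodata sentinel.

Cell footprints are half-open: a cell owns
``[west_edge, east_edge) x (south_edge, north_edge]`` so that any point has
a unique owning cell.  Longitudes are normalized to ``[-180, 180)`` and no
wrap-around across the antimeridian is supported.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
import shapely.geometry

__all__ = [
    "GridGeometry",
    "GeoGrid",
    "UncertaintySurface",
    "RegionMask",
    "GridError",
    "GridFormatError",
    "AlignmentError",
    "OutOfBoundsError",
    "read_grid",
    "write_grid",
    "combine_tiles",
    "resample_bilinear",
    "mask_grid",
    "extract_at_point",
]

DEFAULT_NODATA = -9999.0

#: GeoTIFF tag ids used for georeferencing single-band rasters.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class GridError(ValueError):
    """Base error for raster operations."""


class GridFormatError(GridError):
    """Malformed grid file; message names the offending field."""


class AlignmentError(GridError):
    """Grids/tiles do not share a compatible lattice."""


class OutOfBoundsError(GridError):
    """Query point falls outside the grid bounds (distinct from nodata)."""


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a north-up lat/lon raster with cell-center registration."""

    n_rows: int
    n_cols: int
    west: float
    north: float
    cell_width: float
    cell_height: float

    def __post_init__(self) -> None:
        if self.n_rows <= 0:
            raise GridFormatError(f"n_rows must be positive, got {self.n_rows}")
        if self.n_cols <= 0:
            raise GridFormatError(f"n_cols must be positive, got {self.n_cols}")
        if self.cell_width <= 0:
            raise GridFormatError(f"cell_width must be > 0, got {self.cell_width}")
        if self.cell_height <= 0:
            raise GridFormatError(f"cell_height must be > 0, got {self.cell_height}")
        if not (-180.0 <= self.west < 180.0):
            raise GridFormatError(f"west must lie in [-180, 180), got {self.west}")
        if not (-90.0 < self.north <= 90.0):
            raise GridFormatError(f"north must lie in (-90, 90], got {self.north}")
        if self.south < -90.0 - 1e-9:
            raise GridFormatError(
                f"grid extends below -90 latitude (south edge {self.south})"
            )

    @property
    def south(self) -> float:
        return self.north - self.n_rows * self.cell_height

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.cell_width

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.n_cols) + 0.5) * self.cell_width

    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, north to south."""
        return self.north - (np.arange(self.n_rows) + 0.5) * self.cell_height

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.west + (col + 0.5) * self.cell_width
        lat = self.north - (row + 0.5) * self.cell_height
        return lon, lat

    def contains(self, lon: float, lat: float) -> bool:
        try:
            self.index_of(lon, lat)
        except OutOfBoundsError:
            return False
        return True

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell whose half-open footprint owns the point.

        West and north edges are inclusive, east and south exclusive.
        """
        col = math.floor((lon - self.west) / self.cell_width)
        row = math.floor((self.north - lat) / self.cell_height)
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise OutOfBoundsError(
                f"point ({lon}, {lat}) outside grid bounds "
                f"[{self.west}, {self.east}) x ({self.south}, {self.north}]"
            )
        return row, col

    def aligned(self, other: "GridGeometry") -> bool:
        """True iff all six geometry fields are equal."""
        return self == other


@dataclass
class GeoGrid:
    """A raster of values on a :class:`GridGeometry`; NaN marks nodata."""

    geometry: GridGeometry
    values: np.ndarray
    units: str = ""
    name: str = ""
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise GridError(
                f"values shape {self.values.shape} does not match geometry "
                f"{self.geometry.shape}"
            )
        finite = self.values[~np.isnan(self.values)]
        if np.any(np.isinf(finite)):
            raise GridError("non-nodata grid values must be finite")
        if self.units == "probability" and finite.size and np.any(finite < 0):
            raise GridError("probability grids must be non-negative")

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def copy(self, **changes) -> "GeoGrid":
        grid = GeoGrid(
            geometry=self.geometry,
            values=self.values.copy(),
            units=self.units,
            name=self.name,
            nodata=self.nodata,
        )
        for key, value in changes.items():
            setattr(grid, key, value)
        return grid

    def equals(self, other: "GeoGrid", atol: float = 0.0) -> bool:
        if self.geometry != other.geometry:
            return False
        a, b = self.values, other.values
        if not np.array_equal(np.isnan(a), np.isnan(b)):
            return False
        mask = ~np.isnan(a)
        if atol == 0.0:
            return bool(np.array_equal(a[mask], b[mask]))
        return bool(np.allclose(a[mask], b[mask], atol=atol, rtol=0.0))


@dataclass
class UncertaintySurface:
    """A non-negative 1-SD grid paired with a mean grid of equal geometry."""

    grid: GeoGrid

    def __post_init__(self) -> None:
        vals = self.grid.values
        if np.any(vals[~np.isnan(vals)] < 0):
            raise GridError("uncertainty surface must be non-negative")

    @property
    def geometry(self) -> GridGeometry:
        return self.grid.geometry

    def check_aligned(self, mean_grid: GeoGrid) -> None:
        if not self.geometry.aligned(mean_grid.geometry):
            raise AlignmentError("uncertainty surface not aligned with mean grid")


@dataclass
class RegionMask:
    """A polygonal or grid-backed boolean region.

    Exactly one of ``polygons`` (any shapely geometry) or ``boolean``
    (boolean array plus the geometry it is registered to) is set.
    """

    label: str = ""
    polygons: shapely.Geometry | None = None
    boolean: np.ndarray | None = None
    boolean_geometry: GridGeometry | None = None

    def __post_init__(self) -> None:
        if (self.polygons is None) == (self.boolean is None):
            raise GridError("RegionMask requires exactly one of polygons/boolean")
        if self.boolean is not None:
            self.boolean = np.asarray(self.boolean, dtype=bool)
            if self.boolean_geometry is None:
                raise GridError("grid-backed mask requires boolean_geometry")
            if self.boolean.shape != self.boolean_geometry.shape:
                raise GridError("boolean mask shape does not match its geometry")

    @classmethod
    def from_bounds(
        cls, west: float, south: float, east: float, north: float, label: str = ""
    ) -> "RegionMask":
        return cls(label=label, polygons=shapely.box(west, south, east, north))

    @classmethod
    def from_geojson(cls, path: str | Path, label: str = "") -> "RegionMask":
        with open(path) as fh:
            obj = json.load(fh)
        if obj.get("type") == "FeatureCollection":
            geoms = [shapely.geometry.shape(f["geometry"]) for f in obj["features"]]
            geom = shapely.union_all(geoms)
        elif obj.get("type") == "Feature":
            geom = shapely.geometry.shape(obj["geometry"])
        else:
            geom = shapely.geometry.shape(obj)
        return cls(label=label or str(path), polygons=geom)

    @classmethod
    def from_grid(
        cls, boolean: np.ndarray, geometry: GridGeometry, label: str = ""
    ) -> "RegionMask":
        return cls(label=label, boolean=boolean, boolean_geometry=geometry)

    def rasterize(self, geometry: GridGeometry) -> np.ndarray:
        """Boolean array of ``geometry.shape``: True where cell centers fall
        in the region (boundary counts as inside)."""
        if self.boolean is not None:
            if not geometry.aligned(self.boolean_geometry):
                raise AlignmentError(
                    "grid-backed mask geometry does not match target geometry"
                )
            return self.boolean.copy()
        lon = geometry.lon_centers()
        lat = geometry.lat_centers()
        lon2d, lat2d = np.meshgrid(lon, lat)
        return shapely.intersects_xy(self.polygons, lon2d, lat2d)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_HEADER_FIELDS = (
    "n_rows",
    "n_cols",
    "west",
    "north",
    "cell_width",
    "cell_height",
    "nodata",
)


def _parse_text_header(line: str) -> tuple[GridGeometry, float]:
    parts = line.split()
    if len(parts) != len(_HEADER_FIELDS):
        raise GridFormatError(
            f"header must contain {len(_HEADER_FIELDS)} fields "
            f"({' '.join(_HEADER_FIELDS)}), got {len(parts)}"
        )
    values = {}
    for name, token in zip(_HEADER_FIELDS, parts):
        try:
            values[name] = int(token) if name in ("n_rows", "n_cols") else float(token)
        except ValueError:
            raise GridFormatError(f"header field {name} is not numeric: {token!r}")
    geometry = GridGeometry(
        n_rows=values["n_rows"],
        n_cols=values["n_cols"],
        west=values["west"],
        north=values["north"],
        cell_width=values["cell_width"],
        cell_height=values["cell_height"],
    )
    return geometry, values["nodata"]


def read_text_grid(path: str | Path) -> GeoGrid:
    """Read the plain-text grid dialect (header line, then rows north->south)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise GridFormatError("empty file: missing header line")
        geometry, nodata = _parse_text_header(header)
        try:
            data = np.loadtxt(fh, dtype=float, ndmin=2)
        except ValueError as exc:
            raise GridFormatError(f"malformed data rows: {exc}") from exc
    if data.shape != geometry.shape:
        raise GridFormatError(
            f"data shape {data.shape} does not match header {geometry.shape}"
        )
    values = np.where(data == nodata, np.nan, data)
    return GeoGrid(geometry=geometry, values=values, nodata=nodata, name=path.stem)


def write_text_grid(grid: GeoGrid, path: str | Path) -> None:
    geom = grid.geometry
    data = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(
            f"{geom.n_rows} {geom.n_cols} {geom.west!r} {geom.north!r} "
            f"{geom.cell_width!r} {geom.cell_height!r} {grid.nodata!r}\n"
        )
        np.savetxt(fh, data, fmt="%.17g")


def read_geotiff(path: str | Path, band: int | None = None) -> GeoGrid:
    """Read a single-band float GeoTIFF (pixel-scale + tiepoint tags)."""
    import tifffile

    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) > 1 and band is None:
            raise GridError(
                f"{path} has {len(tif.pages)} bands; a band selector is required"
            )
        page = tif.pages[band if band is not None else 0]
        if page.samplesperpixel != 1:
            raise GridError(f"{path}: interleaved multi-sample TIFFs are unsupported")
        data = np.asarray(page.asarray(), dtype=float)
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise GridFormatError(f"{path} lacks georeferencing tags")
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
        tie = tags[_TAG_MODEL_TIEPOINT].value
        # Tiepoint maps raster position (i, j) = (0, 0) to (west, north).
        west = tie[3] - tie[0] * sx
        north = tie[4] + tie[1] * sy
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
    geometry = GridGeometry(
        n_rows=data.shape[0],
        n_cols=data.shape[1],
        west=west,
        north=north,
        cell_width=sx,
        cell_height=sy,
    )
    values = np.where((data == nodata) | np.isnan(data), np.nan, data)
    return GeoGrid(geometry=geometry, values=values, nodata=nodata, name=path.stem)


def write_geotiff(grid: GeoGrid, path: str | Path) -> None:
    import tifffile

    geom = grid.geometry
    data = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    extratags = [
        (
            _TAG_MODEL_PIXEL_SCALE,
            "d",
            3,
            (geom.cell_width, geom.cell_height, 0.0),
            True,
        ),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, geom.west, geom.north, 0.0),
            True,
        ),
        (_TAG_GDAL_NODATA, "s", 0, repr(grid.nodata), True),
    ]
    tifffile.imwrite(path, data.astype(np.float64), extratags=extratags)


def read_grid(path: str | Path, band: int | None = None) -> GeoGrid:
    """Read a grid, dispatching on extension (.tif/.tiff -> GeoTIFF)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return read_geotiff(path, band=band)
    return read_text_grid(path)


def write_grid(grid: GeoGrid, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        write_geotiff(grid, path)
    else:
        write_text_grid(grid, path)


# ---------------------------------------------------------------------------
# Geometric operations
# ---------------------------------------------------------------------------


def combine_tiles(tiles: Sequence[GeoGrid], atol: float = 1e-6) -> GeoGrid:
    """Mosaic tiles sharing a common cell lattice into one bounding grid.

    Overlapping non-nodata cells must agree within ``atol``; cells covered by
    no tile are nodata.  The result is independent of tile order.
    """
    if not tiles:
        raise GridError("combine_tiles requires at least one tile")
    ref = tiles[0].geometry
    cw, ch = ref.cell_width, ref.cell_height
    for tile in tiles[1:]:
        g = tile.geometry
        if not (
            math.isclose(g.cell_width, cw, abs_tol=1e-12)
            and math.isclose(g.cell_height, ch, abs_tol=1e-12)
        ):
            raise AlignmentError("tiles have differing cell sizes")
        for value, step, what in (
            ((g.west - ref.west) / cw, cw, "west"),
            ((g.north - ref.north) / ch, ch, "north"),
        ):
            if abs(value - round(value)) > 1e-6:
                raise AlignmentError(
                    f"tile {tile.name or '?'} {what} edge off the common lattice"
                )
    west = min(t.geometry.west for t in tiles)
    north = max(t.geometry.north for t in tiles)
    east = max(t.geometry.east for t in tiles)
    south = min(t.geometry.south for t in tiles)
    n_cols = round((east - west) / cw)
    n_rows = round((north - south) / ch)
    geometry = GridGeometry(
        n_rows=n_rows, n_cols=n_cols, west=west, north=north,
        cell_width=cw, cell_height=ch,
    )
    values = np.full(geometry.shape, np.nan)
    for tile in tiles:
        r0 = round((north - tile.geometry.north) / ch)
        c0 = round((tile.geometry.west - west) / cw)
        tr, tc = tile.geometry.shape
        window = values[r0 : r0 + tr, c0 : c0 + tc]
        incoming = tile.values
        both = ~np.isnan(window) & ~np.isnan(incoming)
        if np.any(np.abs(window[both] - incoming[both]) > atol):
            raise GridError(
                f"tile {tile.name or '?'} conflicts with overlap beyond tolerance"
            )
        take = ~np.isnan(incoming)
        window[take] = incoming[take]
    return GeoGrid(
        geometry=geometry, values=values,
        units=tiles[0].units, name=tiles[0].name, nodata=tiles[0].nodata,
    )


def resample_bilinear(src: GeoGrid, target: GridGeometry) -> GeoGrid:
    """Bilinear resampling between cell-center lattices.

    Target centers outside the source center lattice, or with any
    positively-weighted contributing source cell nodata, become nodata.
    """
    sg = src.geometry
    # Fractional index of target centers on the source center lattice.
    u = (target.lon_centers() - (sg.west + 0.5 * sg.cell_width)) / sg.cell_width
    v = ((sg.north - 0.5 * sg.cell_height) - target.lat_centers()) / sg.cell_height
    uu, vv = np.meshgrid(u, v)
    inside = (uu >= 0) & (uu <= sg.n_cols - 1) & (vv >= 0) & (vv <= sg.n_rows - 1)
    if not inside.any():
        raise GridError("target geometry does not overlap the source lattice")
    j0 = np.clip(np.floor(uu).astype(int), 0, sg.n_cols - 1)
    i0 = np.clip(np.floor(vv).astype(int), 0, sg.n_rows - 1)
    fu = np.clip(uu - j0, 0.0, 1.0)
    fv = np.clip(vv - i0, 0.0, 1.0)
    # Collapse zero-weight neighbors so lattice-coincident centers need only
    # the cells that actually contribute.
    j1 = np.where(fu > 0, np.minimum(j0 + 1, sg.n_cols - 1), j0)
    i1 = np.where(fv > 0, np.minimum(i0 + 1, sg.n_rows - 1), i0)
    sv = src.values
    v00 = sv[i0, j0]
    v01 = sv[i0, j1]
    v10 = sv[i1, j0]
    v11 = sv[i1, j1]
    out = (
        (1 - fv) * (1 - fu) * v00
        + (1 - fv) * fu * v01
        + fv * (1 - fu) * v10
        + fv * fu * v11
    )
    out[~inside] = np.nan
    return GeoGrid(
        geometry=target, values=out, units=src.units,
        name=src.name, nodata=src.nodata,
    )


def mask_grid(grid: GeoGrid, mask: RegionMask, mode: str = "keep") -> GeoGrid:
    """Set cells outside (keep) or inside (drop) the mask to nodata."""
    if mode not in ("keep", "drop"):
        raise ValueError(f"mode must be 'keep' or 'drop', got {mode!r}")
    selected = mask.rasterize(grid.geometry)
    if not selected.any():
        warnings.warn(
            f"mask {mask.label or '?'} rasterizes to an empty region",
            stacklevel=2,
        )
    values = grid.values.copy()
    if mode == "keep":
        values[~selected] = np.nan
    else:
        values[selected] = np.nan
    return GeoGrid(
        geometry=grid.geometry, values=values, units=grid.units,
        name=grid.name, nodata=grid.nodata,
    )


def extract_at_point(grid: GeoGrid, lon: float, lat: float) -> float:
    """Value of the cell owning the point (nearest-cell, no interpolation).

    Returns NaN for a nodata cell; raises :class:`OutOfBoundsError` when the
    point lies outside the grid bounds.
    """
    row, col = grid.geometry.index_of(lon, lat)
    return float(grid.values[row, col])
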