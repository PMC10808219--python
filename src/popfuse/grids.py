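"""Raster containers and GeoTIFF I/O for gridded population layers.

All layers in a run share one regular WGS84 geographic lattice; no resampling
is ever performed, and stages that combine grids require exact alignment of
shape and geotransform.  Internally, nodata cells are represented as NaN in a
float array; the integer/float sentinel only exists at the file boundary.

The geotransform follows the GeoTIFF/GDAL pixel-is-area convention: ``west``
and ``north`` are the outer corner of the top-left cell, rows run north to
south, and cell sizes are positive decimal degrees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: Authalic-sphere radius (km) used when no surface-area raster is supplied.
EARTH_RADIUS_KM = 6371.0072

COUNT = "count_per_pixel"
DENSITY = "density_per_km2"
_UNITS = (COUNT, DENSITY)

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113


class AlignmentError(ValueError):
    """Raised when two layers do not share the reference lattice."""


@dataclass(frozen=True)
class GridGeometry:
    """Regular geographic lattice: outer corner of the top-left cell plus cell size."""

    west: float
    north: float
    dx: float  # cell width, decimal degrees, > 0
    dy: float  # cell height, decimal degrees, > 0

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError(f"cell size must be positive, got dx={self.dx}, dy={self.dy}")

    def lat_edges(self, rows: int) -> np.ndarray:
        """Latitudes of the ``rows + 1`` horizontal cell edges, north to south."""
        return self.north - self.dy * np.arange(rows + 1)

    def approx_equal(self, other: "GridGeometry", tol: float = 1e-9) -> bool:
        return (
            abs(self.west - other.west) <= tol
            and abs(self.north - other.north) <= tol
            and abs(self.dx - other.dx) <= tol
            and abs(self.dy - other.dy) <= tol
        )


@dataclass
class PopulationGrid:
    """One product-year raster of population, as count per pixel or density per km²."""

    values: np.ndarray
    geometry: GridGeometry
    unit: str
    year: int
    product_id: str = ""
    crs_tag: str = "WGS84"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("values must be a 2-D array with at least one cell")
        if self.unit not in _UNITS:
            raise ValueError(f"unit must be one of {_UNITS}, got {self.unit!r}")
        if np.isinf(self.values).any():
            raise ValueError("non-nodata values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of nodata cells."""
        return np.isnan(self.values)

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "PopulationGrid":
        return replace(self, values=np.asarray(values, dtype=np.float64),
                       unit=self.unit if unit is None else unit)


@dataclass
class AreaGrid:
    """Surface area of each cell in km²; constant along rows of a geographic grid."""

    values: np.ndarray
    geometry: GridGeometry
    crs_tag: str = "WGS84"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not (self.values > 0).all():
            raise ValueError("cell areas must all be positive")


@dataclass
class ZoneMap:
    """Integer admin-zone labels over the lattice; label 0 means 'no unit'."""

    labels: np.ndarray
    geometry: GridGeometry
    level: str = "level0"
    code_lookup: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        present = np.unique(self.labels)
        present = present[present != 0]
        missing = [int(p) for p in present if int(p) not in self.code_lookup]
        if missing:
            raise ValueError(f"zone labels without a code: {missing}")

    @property
    def codes(self) -> list[str]:
        return [self.code_lookup[int(l)] for l in sorted(self.code_lookup)]

    def label_of(self, code: str) -> int:
        for label, c in self.code_lookup.items():
            if c == code:
                return int(label)
        raise KeyError(code)


def require_aligned(*layers) -> None:
    """Assert that all layers share one shape and geotransform."""
    ref = layers[0]
    ref_shape = ref.values.shape if hasattr(ref, "values") else ref.labels.shape
    for layer in layers[1:]:
        shape = layer.values.shape if hasattr(layer, "values") else layer.labels.shape
        if shape != ref_shape:
            raise AlignmentError(f"shape mismatch: {shape} vs {ref_shape}")
        if not ref.geometry.approx_equal(layer.geometry):
            raise AlignmentError(
                f"geotransform mismatch: {layer.geometry} vs {ref.geometry}"
            )


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def _geotiff_tags(geometry: GridGeometry, nodata: float) -> list[tuple]:
    # Minimal GeoTIFF key directory: geographic model, pixel-is-area, EPSG:4326.
    geokeys = (1, 1, 0, 3,
               1024, 0, 1, 2,
               1025, 0, 1, 1,
               2048, 0, 1, 4326)
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (geometry.dx, geometry.dy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, geometry.west, geometry.north, 0.0)),
        (_TAG_GEOKEYS, "H", len(geokeys), geokeys),
        (_TAG_GDAL_NODATA, "s", 0, _format_nodata(nodata)),
    ]


def _format_nodata(nodata: float) -> str:
    if float(nodata).is_integer():
        return str(int(nodata))
    return repr(float(nodata))


def write_grid(grid: PopulationGrid, out_dir: str | Path, dtype: str = "F32",
               name: str = "GlobPOP", resolution_tag: str = "30arc") -> Path:
    """Write a grid as single-band GeoTIFF under the 5-field naming convention.

    The filename is ``<name>_<Count|Density>_<resolution>_<year>_<I32|F32>.tif``.
    Count layers may be written as I32 (values rounded half-up) or F32; density
    layers are always F32 and requesting I32 for them is an error.
    """
    if dtype not in ("I32", "F32"):
        raise ValueError(f"dtype must be 'I32' or 'F32', got {dtype!r}")
    if grid.unit == DENSITY and dtype == "I32":
        raise ValueError("density grids are published as Float32; I32 not allowed")
    unit_field = "Count" if grid.unit == COUNT else "Density"
    fname = f"{name}_{unit_field}_{resolution_tag}_{grid.year}_{dtype}.tif"
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / fname

    data = grid.values
    if dtype == "I32":
        # round half-up, matching the published integer count layers
        filled = np.where(np.isnan(data), grid.nodata, np.floor(data + 0.5))
        arr = filled.astype(np.int32)
    else:
        arr = np.where(np.isnan(data), grid.nodata, data).astype(np.float32)
    tifffile.imwrite(path, arr, extratags=_geotiff_tags(grid.geometry, grid.nodata))
    return path


def write_zone_map(zones: ZoneMap, out_dir: str | Path, stem: str = "zones") -> tuple[Path, Path]:
    """Write a zone map as integer GeoTIFF plus a (label, code) CSV lookup."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tif = out_dir / f"{stem}.tif"
    csv = out_dir / f"{stem}_codes.csv"
    tifffile.imwrite(tif, zones.labels.astype(np.int32),
                     extratags=_geotiff_tags(zones.geometry, 0))
    pd.DataFrame(
        {"label": sorted(zones.code_lookup),
         "code": [zones.code_lookup[k] for k in sorted(zones.code_lookup)]}
    ).to_csv(csv, index=False)
    return tif, csv


def _read_geotiff(path: str | Path) -> tuple[np.ndarray, GridGeometry, float | None]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"{path}: expected a single-band raster, found {len(tif.pages)} pages")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(f"{path}: expected one sample per pixel")
        arr = page.asarray()
        tags = page.tags
        scale = tags.get(_TAG_PIXEL_SCALE)
        tie = tags.get(_TAG_TIEPOINT)
        keys = tags.get(_TAG_GEOKEYS)
        if scale is None or tie is None:
            raise ValueError(f"{path}: missing GeoTIFF geotransform tags")
        if keys is not None:
            kv = keys.value
            model = {kv[i]: kv[i + 3] for i in range(4, len(kv), 4)}.get(1024)
            if model is not None and model != 2:
                raise ValueError(f"{path}: not in a geographic coordinate system")
        geometry = GridGeometry(west=float(tie.value[3]), north=float(tie.value[4]),
                                dx=float(scale.value[0]), dy=float(scale.value[1]))
        ntag = tags.get(_TAG_GDAL_NODATA)
        nodata = float(ntag.value) if ntag is not None else None
    return arr, geometry, nodata


def read_grid(path: str | Path, unit: str, year: int, product_id: str = "") -> PopulationGrid:
    """Read a single-band geographic GeoTIFF into a :class:`PopulationGrid`.

    Nodata cells become NaN.  The file must already sit on the run's reference
    lattice; this reader never reprojects or resamples.
    """
    arr, geometry, nodata = _read_geotiff(path)
    values = arr.astype(np.float64)
    if nodata is not None:
        values[arr == nodata] = np.nan
    return PopulationGrid(values=values, geometry=geometry, unit=unit, year=year,
                          product_id=product_id,
                          nodata=nodata if nodata is not None else -9999.0)


def read_zone_map(tif_path: str | Path, csv_path: str | Path, level: str = "level0") -> ZoneMap:
    arr, geometry, _ = _read_geotiff(tif_path)
    lookup_df = pd.read_csv(csv_path, dtype={"label": int, "code": str})
    lookup = dict(zip(lookup_df["label"], lookup_df["code"]))
    return ZoneMap(labels=arr.astype(np.int64), geometry=geometry, level=level,
                   code_lookup=lookup)


# ---------------------------------------------------------------------------
# Area and unit conversion
# ---------------------------------------------------------------------------

def pixel_area(geometry: GridGeometry, rows: int, cols: int,
               sphere_radius_km: float = EARTH_RADIUS_KM) -> AreaGrid:
    """Spherical surface area (km²) of every cell of a regular geographic grid.

    A cell spanning longitudes [λ1, λ2] and latitudes [φ1, φ2] has area
    R² (λ2 − λ1) (sin φ2 − sin φ1) with angles in radians, so the area depends
    only on the row.
    """
    edges = geometry.lat_edges(rows)
    if edges.max() > 90 + 1e-9 or edges.min() < -90 - 1e-9:
        raise ValueError("grid extends beyond the poles")
    edges_rad = np.deg2rad(np.clip(edges, -90.0, 90.0))
    band = np.sin(edges_rad[:-1]) - np.sin(edges_rad[1:])  # rows run N -> S
    row_area = sphere_radius_km**2 * math.radians(geometry.dx) * band
    return AreaGrid(values=np.repeat(row_area[:, None], cols, axis=1), geometry=geometry)


def density_to_count(grid: PopulationGrid, area: AreaGrid) -> PopulationGrid:
    """Convert density per km² to count per pixel by multiplying with cell area."""
    if grid.unit != DENSITY:
        raise ValueError(f"expected a density grid, got unit={grid.unit!r}")
    require_aligned(grid, area)
    return grid.with_values(grid.values * area.values, unit=COUNT)


def count_to_density(grid: PopulationGrid, area: AreaGrid) -> PopulationGrid:
    """Exact inverse of :func:`density_to_count` on non-nodata cells."""
    if grid.unit != COUNT:
        raise ValueError(f"expected a count grid, got unit={grid.unit!r}")
    require_aligned(grid, area)
    return grid.with_values(grid.values / area.values, unit=DENSITY)


def zonal_sum(grid: PopulationGrid, zones: ZoneMap) -> pd.Series:
    """Sum non-nodata count pixels within each admin zone.

    Returns a Series indexed by unit code; zones containing no data sum to 0
    with a warning.  Pixels with label 0 are outside every unit and excluded.
    """
    if grid.unit != COUNT:
        raise ValueError("zonal_sum operates on count grids")
    require_aligned(grid, zones)
    labels = zones.labels.ravel()
    values = np.nan_to_num(grid.values.ravel(), nan=0.0)
    sums = np.bincount(labels, weights=values)
    out = {}
    empty = []
    for label in sorted(zones.code_lookup):
        code = zones.code_lookup[label]
        total = float(sums[label]) if label < len(sums) else 0.0
        if not np.any((zones.labels == label) & ~grid.mask):
            empty.append(code)
        out[code] = total
    if empty:
        warnings.warn(f"zones with no data pixels: {empty}", stacklevel=2)
    return pd.Series(out, name=f"{grid.product_id}_{grid.year}", dtype=float)
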