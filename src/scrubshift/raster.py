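"""Single-band georeferenced grids and their GeoTIFF / GeoJSON plumbing.

A :class:`GridRaster` is the one container every stage of the pipeline
passes around: a 2-D array of cell values (metres for height layers,
small integer codes for class layers), an affine placement on the ground,
an opaque CRS tag and a nodata sentinel.  The convention is the usual
"north-up" raster one: row 0 is the northern edge, ``origin_x/origin_y``
is the outer corner of cell (0, 0), and cell sizes are strictly positive.

GeoTIFF support is deliberately minimal — single band, the GeoTIFF
ModelPixelScale/ModelTiepoint tags for placement, the GDAL nodata tag,
and the GeoAsciiParams tag to carry the CRS identifier.  Reprojection is
out of scope: all inputs to one analysis must already share a CRS tag.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
import tifffile
from shapely.geometry import box as _box
from shapely.geometry import shape as _shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "GridTransform",
    "GridRaster",
    "SitePolygons",
    "RasterIOError",
    "CRSMismatchError",
    "DEFAULT_HEIGHT_NODATA",
    "DEFAULT_CLASS_NODATA",
    "read_raster",
    "write_raster",
    "read_geojson_geometries",
    "load_site_polygons",
    "clip_to_site",
]

#: default nodata sentinel for continuous height rasters (metres)
DEFAULT_HEIGHT_NODATA = -9999.0
#: default nodata sentinel for small-integer class rasters
DEFAULT_CLASS_NODATA = 255

# TIFF tag codes used for georeferencing
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_ASCII_PARAMS = 34737
_TAG_GDAL_NODATA = 42113


class RasterIOError(ValueError):
    """Raised for unreadable, non-georeferenced or multi-band raster files."""


class CRSMismatchError(ValueError):
    """Raised when two layers that must share a coordinate system do not."""


@dataclass(frozen=True)
class GridTransform:
    """Affine placement of a north-up grid.

    ``origin_x``/``origin_y`` locate the outer (top-left) corner of cell
    (0, 0); ``cell_w``/``cell_h`` are the cell footprint in metres and must
    be strictly positive.  y decreases with increasing row index.
    """

    origin_x: float
    origin_y: float
    cell_w: float
    cell_h: float

    def __post_init__(self) -> None:
        for name in ("cell_w", "cell_h"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {v!r}")
        if not (math.isfinite(self.origin_x) and math.isfinite(self.origin_y)):
            raise ValueError("raster origin must be finite")

    @property
    def cell_area(self) -> float:
        return self.cell_w * self.cell_h

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Ground coordinates of the centre of cell (row, col)."""
        x = self.origin_x + (col + 0.5) * self.cell_w
        y = self.origin_y - (row + 0.5) * self.cell_h
        return x, y

    def centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) centre-coordinate arrays for a grid of the given shape."""
        rows, cols = shape
        xs = self.origin_x + (np.arange(cols) + 0.5) * self.cell_w
        ys = self.origin_y - (np.arange(rows) + 0.5) * self.cell_h
        return np.meshgrid(xs, ys)

    def index_of(self, x: float | np.ndarray, y: float | np.ndarray):
        """(row, col) of the cell containing ground point (x, y).

        Points exactly on a cell's left/top edge belong to that cell.
        """
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_w).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.cell_h).astype(int)
        return row, col

    def bounds(self, shape: tuple[int, int]) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the grid extent."""
        rows, cols = shape
        return (
            self.origin_x,
            self.origin_y - rows * self.cell_h,
            self.origin_x + cols * self.cell_w,
            self.origin_y,
        )


@dataclass
class GridRaster:
    """A single-band georeferenced cell grid.

    Invariants enforced at construction: the array is 2-D, cell sizes are
    positive and finite, and every cell is either the nodata sentinel or a
    finite number.
    """

    values: np.ndarray
    transform: GridTransform
    crs_tag: str = ""
    nodata: float = DEFAULT_HEIGHT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"raster values must be 2-D, got {self.values.ndim}-D")
        bad = ~np.isfinite(self.values) & ~self._nodata_mask(self.values)
        if bad.any():
            raise ValueError("raster contains non-finite cells that are not nodata")

    def _nodata_mask(self, arr: np.ndarray) -> np.ndarray:
        if isinstance(self.nodata, float) and math.isnan(self.nodata):
            return np.isnan(arr)
        return arr == self.nodata

    # -- derived views ------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def cell_area(self) -> float:
        """Ground area of one cell in m² (cell width × cell height)."""
        return self.transform.cell_area

    @property
    def data_mask(self) -> np.ndarray:
        """Boolean grid, True where the cell carries data."""
        return ~self._nodata_mask(self.values)

    @property
    def n_data(self) -> int:
        return int(self.data_mask.sum())

    def data_values(self) -> np.ndarray:
        return self.values[self.data_mask]

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "GridRaster":
        """A new raster on the same grid with different cell values."""
        return GridRaster(
            values=values,
            transform=self.transform,
            crs_tag=self.crs_tag,
            nodata=self.nodata if nodata is None else nodata,
        )

    def same_grid(self, other: "GridRaster") -> bool:
        return self.shape == other.shape and self.transform == other.transform

    def require_same_grid(self, other: "GridRaster", what: str = "rasters") -> None:
        if self.crs_tag != other.crs_tag:
            raise CRSMismatchError(
                f"{what} have different CRS tags: {self.crs_tag!r} vs {other.crs_tag!r}"
            )
        if not self.same_grid(other):
            raise ValueError(
                f"{what} are not on the same grid: "
                f"shape {self.shape} vs {other.shape}, "
                f"transform {self.transform} vs {other.transform}"
            )


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def write_raster(raster: GridRaster, path: str | os.PathLike) -> None:
    """Write a :class:`GridRaster` as a single-band georeferenced GeoTIFF.

    Integer-coded rasters are written with their integer dtype; height
    rasters keep their float width, so a read-back round-trip is
    value-identical.
    """
    t = raster.transform
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (float(t.cell_w), float(t.cell_h), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, float(t.origin_x), float(t.origin_y), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(raster.nodata)
         if isinstance(raster.nodata, float) else str(raster.nodata)),
        (_TAG_GEO_ASCII_PARAMS, "s", 0, raster.crs_tag + "|"),
    ]
    tifffile.imwrite(path, raster.values, extratags=extratags)


def _tag_value(page, code):
    tag = page.tags.get(code)
    return None if tag is None else tag.value


def read_raster(path: str | os.PathLike) -> GridRaster:
    """Read a single-band georeferenced GeoTIFF into a :class:`GridRaster`.

    Raises :class:`RasterIOError` for missing files, missing georeference
    tags, or multi-band input (the error names the band count).
    """
    if not os.path.exists(path):
        raise RasterIOError(f"raster file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        n_bands = len(tif.pages) if len(tif.pages) > 1 else page.samplesperpixel
        if n_bands != 1:
            raise RasterIOError(
                f"expected single band, file {path} has {n_bands} bands"
            )
        values = page.asarray()
        scale = _tag_value(page, _TAG_MODEL_PIXEL_SCALE)
        tiepoint = _tag_value(page, _TAG_MODEL_TIEPOINT)
        if scale is None or tiepoint is None:
            raise RasterIOError(
                f"file {path} is not georeferenced "
                "(missing ModelPixelScale/ModelTiepoint tags)"
            )
        i, j, _k, x, y, _z = tiepoint[:6]
        transform = GridTransform(
            origin_x=float(x) - float(j) * float(scale[0]),
            origin_y=float(y) + float(i) * float(scale[1]),
            cell_w=float(scale[0]),
            cell_h=float(scale[1]),
        )
        crs_raw = _tag_value(page, _TAG_GEO_ASCII_PARAMS) or ""
        crs_tag = str(crs_raw).rstrip("\x00|")
        nodata_raw = _tag_value(page, _TAG_GDAL_NODATA)
        if nodata_raw is None:
            nodata = (DEFAULT_CLASS_NODATA if np.issubdtype(values.dtype, np.integer)
                      else DEFAULT_HEIGHT_NODATA)
        else:
            nodata = float(nodata_raw)
            if np.issubdtype(values.dtype, np.integer):
                nodata = int(nodata)
    return GridRaster(values=values, transform=transform, crs_tag=crs_tag, nodata=nodata)


# ---------------------------------------------------------------------------
# Site polygons (boundary + exclusions) and clipping
# ---------------------------------------------------------------------------

@dataclass
class SitePolygons:
    """Site boundary and optional excluded features (buildings, structures).

    ``denominator_area_m2`` optionally overrides the polygon-derived area as
    the denominator used for all cover percentages — sites are often quoted
    against an official reserve area rather than the digitised boundary.
    """

    boundary: BaseGeometry
    exclusions: list[BaseGeometry] = field(default_factory=list)
    denominator_area_m2: float | None = None
    crs_tag: str = ""

    def __post_init__(self) -> None:
        if not self.boundary.is_valid:
            raise ValueError("site boundary polygon is invalid (self-intersecting?)")
        if self.boundary.area <= 0:
            raise ValueError("site boundary polygon has non-positive area")
        for i, ex in enumerate(self.exclusions):
            if not ex.intersects(self.boundary):
                warnings.warn(
                    f"exclusion polygon {i} does not intersect the site boundary",
                    stacklevel=2,
                )
        if self.denominator_area_m2 is not None and self.denominator_area_m2 <= 0:
            raise ValueError("denominator_area_m2 must be positive")

    @property
    def site_area_m2(self) -> float:
        """The cover-percentage denominator: explicit override, else polygon area."""
        if self.denominator_area_m2 is not None:
            return float(self.denominator_area_m2)
        return float(self.boundary.area)


def read_geojson_geometries(path: str | os.PathLike) -> list[BaseGeometry]:
    """All geometries from a GeoJSON file (FeatureCollection, Feature or geometry)."""
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("type") == "FeatureCollection":
        return [_shape(f["geometry"]) for f in obj["features"]]
    if obj.get("type") == "Feature":
        return [_shape(obj["geometry"])]
    return [_shape(obj)]


def load_site_polygons(
    boundary_path: str | os.PathLike,
    exclusions_path: str | os.PathLike | None = None,
    denominator_area_m2: float | None = None,
    crs_tag: str = "",
) -> SitePolygons:
    """Load boundary (unioned if multiple features) and exclusion polygons."""
    boundary = shapely.union_all(read_geojson_geometries(boundary_path))
    exclusions = (
        read_geojson_geometries(exclusions_path) if exclusions_path is not None else []
    )
    return SitePolygons(
        boundary=boundary,
        exclusions=exclusions,
        denominator_area_m2=denominator_area_m2,
        crs_tag=crs_tag,
    )


def clip_to_site(raster: GridRaster, site: SitePolygons) -> GridRaster:
    """Mask a raster to the site: outside-boundary and excluded cells → nodata.

    A cell belongs to a polygon iff its CENTRE does; centres exactly on the
    polygon edge count as inside (closed test).  Retained cells are
    unchanged and the grid extent and transform are untouched, so clipping
    is idempotent.
    """
    if site.crs_tag and raster.crs_tag and site.crs_tag != raster.crs_tag:
        raise CRSMismatchError(
            f"raster CRS {raster.crs_tag!r} != site CRS {site.crs_tag!r}"
        )
    extent = _box(*raster.transform.bounds(raster.shape))
    if not site.boundary.intersects(extent):
        raise ValueError(
            "site boundary is disjoint from the raster extent; "
            "clipping would produce an empty raster"
        )
    X, Y = raster.transform.centers(raster.shape)
    keep = shapely.intersects_xy(site.boundary, X.ravel(), Y.ravel()).reshape(raster.shape)
    for ex in site.exclusions:
        inside_ex = shapely.intersects_xy(ex, X.ravel(), Y.ravel()).reshape(raster.shape)
        keep &= ~inside_ex
    out = raster.values.copy()
    out[~keep] = raster.nodata
    return raster.with_values(out)
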