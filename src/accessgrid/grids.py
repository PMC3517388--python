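"""Georeferenced grid and vector-layer data model with file I/O.

A :class:`Grid` is a rectangular raster in a projected coordinate system
measured in meters.  Row 0 is the northernmost row, indexing is 0-based and
row-major, and a cell's location is its center.  ``origin_x``/``origin_y``
are the map coordinates of the *outer* (north-west) corner of cell (0, 0).

Two on-disk formats are supported: ESRI ASCII grids (plain text, handy for
version-controlled fixtures) and single-band GeoTIFF (via :mod:`tifffile`,
using the ModelPixelScale / ModelTiepoint / GDAL_NODATA tags).  Vector
layers round-trip through GeoJSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "Grid",
    "VectorLayer",
    "GridAlignmentError",
    "read_grid",
    "write_grid",
    "resample_to",
    "read_vector",
    "write_vector",
]

GridKind = Literal["continuous", "categorical"]

# GeoTIFF tag codes understood by GDAL and friends.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class GridAlignmentError(ValueError):
    """Raised when an operation requires aligned grids and they are not."""


@dataclass
class Grid:
    """A georeferenced raster: values plus origin, cell size and nodata.

    Parameters
    ----------
    values
        2-D array.  Class codes (integers) for categorical grids,
        numbers for continuous ones.
    origin_x, origin_y
        Map coordinates (meters) of the outer NW corner of cell (0, 0).
    cell_size
        Square cell edge length in meters (> 0).
    nodata
        Sentinel marking cells with no value.
    kind
        ``"continuous"`` or ``"categorical"``.
    """

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 90.0
    nodata: float = -9999
    kind: GridKind = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("grid values must be a non-empty 2-D array")
        if not (self.cell_size > 0):
            raise ValueError("cell_size must be positive")
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown grid kind {self.kind!r}")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def aligned_with(self, other: "Grid") -> bool:
        """True iff identical origin, cell size and shape."""
        return (
            self.shape == other.shape
            and math.isclose(self.cell_size, other.cell_size, rel_tol=0, abs_tol=1e-9)
            and math.isclose(self.origin_x, other.origin_x, rel_tol=0, abs_tol=1e-6)
            and math.isclose(self.origin_y, other.origin_y, rel_tol=0, abs_tol=1e-6)
        )

    def require_aligned(self, other: "Grid", what: str = "grid") -> None:
        if not self.aligned_with(other):
            raise GridAlignmentError(
                f"{what} is not aligned (origin/cell size/shape must match exactly); "
                "resample explicitly with resample_to()"
            )

    def cell_center(self, row: int | np.ndarray, col: int | np.ndarray):
        """Map coordinates of cell centers."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def index_of(self, x: float | np.ndarray, y: float | np.ndarray):
        """(row, col) of the cell containing map point (x, y).

        Points on a cell's south or east edge belong to the next cell,
        consistent with half-open pixel extents.
        """
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def contains_index(self, row, col) -> np.ndarray:
        return (np.asarray(row) >= 0) & (np.asarray(row) < self.nrows) & \
            (np.asarray(col) >= 0) & (np.asarray(col) < self.ncols)

    @property
    def valid_mask(self) -> np.ndarray:
        v = self.values
        if np.issubdtype(v.dtype, np.floating):
            return ~(np.isnan(v) | (v == self.nodata))
        return v != self.nodata

    def copy(self) -> "Grid":
        return replace(self, values=self.values.copy())

    def like(self, values: np.ndarray, kind: GridKind | None = None,
             nodata: float | None = None) -> "Grid":
        """New grid sharing this grid's georeferencing."""
        return Grid(
            values=np.asarray(values),
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=self.cell_size,
            nodata=self.nodata if nodata is None else nodata,
            kind=self.kind if kind is None else kind,
        )


@dataclass
class VectorLayer:
    """A homogeneous set of vector features (shapely geometry + attributes)."""

    geometry_type: Literal["point", "line", "polygon"]
    features: list[tuple[BaseGeometry, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ok = {
            "point": ("Point", "MultiPoint"),
            "line": ("LineString", "MultiLineString"),
            "polygon": ("Polygon", "MultiPolygon"),
        }[self.geometry_type]
        for geom, _ in self.features:
            if geom.geom_type not in ok:
                raise ValueError(
                    f"{geom.geom_type} feature in a {self.geometry_type} layer"
                )
            if geom.is_empty or not geom.is_valid:
                raise ValueError("empty or invalid geometry in vector layer")

    def __len__(self) -> int:
        return len(self.features)

    def geometries(self) -> list[BaseGeometry]:
        return [g for g, _ in self.features]


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

def _is_integer_grid(grid: Grid) -> bool:
    return np.issubdtype(grid.values.dtype, np.integer)


def read_grid(path: str | Path, kind: GridKind = "continuous") -> Grid:
    """Read a GeoTIFF or ESRI ASCII grid.

    Categorical grids are read verbatim (integer codes, no interpolation).
    Raises on missing files, unreadable formats and non-square cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".asc", ".agr", ".grd", ".txt"):
        return _read_ascii_grid(path, kind)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_geotiff(path, kind)
    raise ValueError(f"unsupported raster format: {path.suffix!r}")


def write_grid(grid: Grid, path: str | Path) -> Path:
    """Write a grid to GeoTIFF or ESRI ASCII; round-trips are bit-faithful
    for integer grids and within float precision otherwise."""
    path = Path(path)
    if path.suffix.lower() in (".asc", ".agr", ".grd", ".txt"):
        _write_ascii_grid(grid, path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        _write_geotiff(grid, path)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r}")
    return path


def _read_ascii_grid(path: Path, kind: GridKind) -> Grid:
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not rows and key in (
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "nodata_value", "dx", "dy",
            ):
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header and req != "cellsize":
            raise ValueError(f"ASCII grid missing {req}")
    if "cellsize" not in header:
        if "dx" in header and "dy" in header:
            if header["dx"] != header["dy"]:
                raise ValueError("non-square cells are not supported")
            header["cellsize"] = header["dx"]
        else:
            raise ValueError("ASCII grid missing cellsize")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    values = np.concatenate(rows).reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    else:  # center-registered variant
        xll = header.get("xllcenter", 0.0) - cell / 2
        yll = header.get("yllcenter", 0.0) - cell / 2
    if kind == "categorical":
        if not np.all(np.isclose(values, np.round(values))):
            raise ValueError("categorical grid contains non-integer codes")
        values = values.astype(np.int64)
        nodata = int(nodata)
    return Grid(values, origin_x=xll, origin_y=yll + nrows * cell,
                cell_size=cell, nodata=nodata, kind=kind)


def _write_ascii_grid(grid: Grid, path: Path) -> None:
    nrows, ncols = grid.shape
    yll = grid.origin_y - nrows * grid.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.origin_x:.6f}\n")
        fh.write(f"yllcorner {yll:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        if _is_integer_grid(grid):
            fh.write(f"NODATA_value {int(grid.nodata)}\n")
            for row in grid.values:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")
        else:
            fh.write(f"NODATA_value {grid.nodata:.6f}\n")
            vals = np.where(np.isnan(grid.values), grid.nodata, grid.values)
            for row in vals:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_geotiff(path: Path, kind: GridKind) -> Grid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path} has no georeferencing tags")
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
        if not math.isclose(sx, sy, rel_tol=1e-9):
            raise ValueError("non-square cells are not supported")
        tp = tags[_TAG_MODEL_TIEPOINT].value
        # tiepoint: raster (i, j, k) -> model (x, y, z); stored at pixel (0,0)
        origin_x = tp[3] - tp[0] * sx
        origin_y = tp[4] + tp[1] * sy
        nodata: float = -9999
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    if values.ndim != 2:
        raise ValueError("only single-band rasters are supported")
    if kind == "categorical":
        values = values.astype(np.int64)
        nodata = int(nodata)
    return Grid(values, origin_x=origin_x, origin_y=origin_y, cell_size=sx,
                nodata=nodata, kind=kind)


def _write_geotiff(grid: Grid, path: Path) -> None:
    import tifffile

    cs = float(grid.cell_size)
    nd = int(grid.nodata) if _is_integer_grid(grid) else float(grid.nodata)
    scale = (cs, cs, 0.0)
    tiepoint = (0.0, 0.0, 0.0, float(grid.origin_x), float(grid.origin_y), 0.0)
    nodata_ascii = (str(nd) + "\x00").encode("ascii")
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, scale, True),
        (_TAG_MODEL_TIEPOINT, "d", 6, tiepoint, True),
        (_TAG_GDAL_NODATA, "s", len(nodata_ascii), nodata_ascii, True),
    ]
    tifffile.imwrite(path, grid.values, extratags=extratags)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to(grid: Grid, target: Grid, method: str | None = None) -> Grid:
    """Resample ``grid`` onto the alignment of ``target``.

    ``method`` defaults to ``"nearest"`` for categorical grids and
    ``"bilinear"`` for continuous ones; bilinear on a categorical grid is
    an error.  Nearest-neighbour output contains only codes present in the
    input.
    """
    if method is None:
        method = "nearest" if grid.kind == "categorical" else "bilinear"
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    if method == "bilinear" and grid.kind == "categorical":
        raise ValueError("bilinear resampling is not valid for categorical grids")

    rows = np.arange(target.nrows)
    cols = np.arange(target.ncols)
    cx = target.origin_x + (cols + 0.5) * target.cell_size
    cy = target.origin_y - (rows + 0.5) * target.cell_size
    # fractional source indices of target cell centers
    col_f = (cx - grid.origin_x) / grid.cell_size - 0.5
    row_f = (grid.origin_y - cy) / grid.cell_size - 0.5
    cgrid, rgrid = np.meshgrid(col_f, row_f)

    if method == "nearest":
        ri = np.clip(np.rint(rgrid).astype(int), 0, grid.nrows - 1)
        ci = np.clip(np.rint(cgrid).astype(int), 0, grid.ncols - 1)
        out = grid.values[ri, ci]
    else:
        from scipy.ndimage import map_coordinates

        out = map_coordinates(
            grid.values.astype(float), [rgrid, cgrid], order=1, mode="nearest"
        )
    return Grid(out, origin_x=target.origin_x, origin_y=target.origin_y,
                cell_size=target.cell_size, nodata=grid.nodata, kind=grid.kind)


# ---------------------------------------------------------------------------
# Vector I/O (GeoJSON)
# ---------------------------------------------------------------------------

_GEOJSON_KIND = {
    "Point": "point", "MultiPoint": "point",
    "LineString": "line", "MultiLineString": "line",
    "Polygon": "polygon", "MultiPolygon": "polygon",
}


def read_vector(path: str | Path) -> VectorLayer:
    """Read a GeoJSON FeatureCollection into a :class:`VectorLayer`."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    feats = []
    kind = None
    for f in doc.get("features", []):
        geom = shape(f["geometry"])
        k = _GEOJSON_KIND.get(geom.geom_type)
        if k is None:
            raise ValueError(f"unsupported geometry type {geom.geom_type}")
        kind = kind or k
        if k != kind:
            raise ValueError("mixed geometry types in one layer")
        feats.append((geom, dict(f.get("properties") or {})))
    if kind is None:
        raise ValueError("empty FeatureCollection")
    return VectorLayer(geometry_type=kind, features=feats)


def write_vector(layer: VectorLayer, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(g), "properties": attrs}
            for g, attrs in layer.features
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)
    return path
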