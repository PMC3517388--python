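"""Friction-surface construction and the scenario speed model.

The merged cost surface is a categorical grid built from a 13-class
landcover raster plus rasterized rivers, water bodies and a 3-class road
network.  Merge precedence is landcover < water < rivers < roads, so a road
crossing a river stays traversable (the crossing cell is a bridge).

The speed model maps (class, scenario) to a travel speed in km/h and a
locomotion mode.  Water bodies are barriers (speed 0) in every scenario:
scenario 1 is walking everywhere, scenario 2 walks off-road and cycles at
10 km/h on roads, scenario 3 walks off-road and rides motorized transport
on national (50 km/h) and district (20 km/h) roads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry.base import BaseGeometry

from ._util import round_half_up_pct
from .grids import Grid, VectorLayer

__all__ = [
    "WATER_CODE",
    "ROAD_CODES",
    "LANDCOVER_CODES",
    "ClassCode",
    "SpeedTable",
    "Facility",
    "FacilityCleanReport",
    "load_speed_table",
    "default_speed_table",
    "speed_for",
    "rasterize_lines",
    "rasterize_polygons",
    "merge_cost_surface",
    "clean_facilities",
]

WATER_CODE = 11
ROAD_CODES = {"national": 14, "district": 15, "rural": 16}
LANDCOVER_CODES = tuple(c for c in range(1, 14))  # includes water (11)


@dataclass(frozen=True)
class ClassCode:
    code: int
    name: str
    category: str  # landcover | road | water


@dataclass(frozen=True)
class Facility:
    """A primary health facility with a catchment-population capacity."""

    id: str
    x: float
    y: float
    capacity: float
    ftype: str = "health_centre"
    row: int = -1
    col: int = -1
    relocated: bool = False


@dataclass(frozen=True)
class FacilityCleanReport:
    n_total: int
    n_missing_both: int
    n_missing_coords_only: int
    n_missing_capacity_only: int
    n_included: int
    n_relocated: int

    def __post_init__(self) -> None:
        expected = (self.n_total - self.n_missing_both
                    - self.n_missing_coords_only - self.n_missing_capacity_only)
        if self.n_included != expected:
            raise ValueError("inclusion count inconsistent with exclusion tallies")

    @property
    def n_excluded(self) -> int:
        return self.n_total - self.n_included

    def _pct(self, n: int) -> float:
        return round_half_up_pct(n, self.n_total)

    @property
    def pct_included(self) -> float:
        return self._pct(self.n_included)

    @property
    def pct_excluded(self) -> float:
        return self._pct(self.n_excluded)

    @property
    def pct_missing_both(self) -> float:
        return self._pct(self.n_missing_both)

    @property
    def pct_missing_coords_only(self) -> float:
        return self._pct(self.n_missing_coords_only)

    @property
    def pct_missing_capacity_only(self) -> float:
        return self._pct(self.n_missing_capacity_only)

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_missing_both": self.n_missing_both,
            "n_missing_coords_only": self.n_missing_coords_only,
            "n_missing_capacity_only": self.n_missing_capacity_only,
            "n_included": self.n_included,
            "n_relocated": self.n_relocated,
            "pct_included": self.pct_included,
            "pct_excluded": self.pct_excluded,
            "pct_missing_both": self.pct_missing_both,
            "pct_missing_coords_only": self.pct_missing_coords_only,
            "pct_missing_capacity_only": self.pct_missing_capacity_only,
        }


class SpeedTable:
    """Scenario -> class -> (speed km/h, mode) lookup."""

    def __init__(self, scenarios: Mapping[int, Mapping[int, tuple[float, str | None]]],
                 classes: Mapping[int, ClassCode]):
        self.scenarios = {int(s): {int(c): (float(v), m) for c, (v, m) in table.items()}
                          for s, table in scenarios.items()}
        self.classes = dict(classes)
        self._validate()

    def _validate(self) -> None:
        for s, table in self.scenarios.items():
            if s not in (1, 2, 3):
                raise ValueError(f"unknown scenario {s}")
            for code, (speed, mode) in table.items():
                cc = self.classes.get(code)
                if cc is None:
                    raise ValueError(f"speed given for unknown class {code}")
                if cc.category == "water":
                    if speed != 0.0:
                        raise ValueError("water must be a barrier in every scenario")
                elif speed <= 0:
                    raise ValueError(f"non-positive speed for traversable class {code}")

    def speed_for(self, cell_class: int, scenario: int) -> tuple[float, str | None]:
        """Speed (km/h; 0.0 means barrier) and mode for a class and scenario."""
        try:
            table = self.scenarios[int(scenario)]
        except KeyError:
            raise ValueError(f"unknown scenario {scenario!r}") from None
        try:
            return table[int(cell_class)]
        except KeyError:
            raise ValueError(f"unknown class code {cell_class!r}") from None

    def is_barrier(self, cell_class: int, scenario: int = 1) -> bool:
        return self.speed_for(cell_class, scenario)[0] == 0.0

    def barrier_codes(self) -> set[int]:
        return {c for c, cc in self.classes.items() if cc.category == "water"}

    def known_codes(self) -> set[int]:
        return set(self.classes)


def load_speed_table(path: str | Path | None = None) -> SpeedTable:
    """Load a speed table from YAML; with no path, the shipped default."""
    if path is None:
        text = resources.files("accessgrid.data").joinpath("speeds.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    classes = {int(c): ClassCode(int(c), d["name"], d["category"])
               for c, d in doc["classes"].items()}
    scenarios = {
        int(s): {int(c): (float(e["speed"]), e["mode"]) for c, e in table.items()}
        for s, table in doc["scenarios"].items()
    }
    return SpeedTable(scenarios, classes)


_DEFAULT_TABLE: SpeedTable | None = None


def default_speed_table() -> SpeedTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_speed_table()
    return _DEFAULT_TABLE


def speed_for(cell_class: int, scenario: int,
              table: SpeedTable | None = None) -> tuple[float, str | None]:
    """Module-level convenience for :meth:`SpeedTable.speed_for`."""
    return (table or default_speed_table()).speed_for(cell_class, scenario)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _segment_cells(u0: float, v0: float, u1: float, v1: float,
                   nrows: int, ncols: int) -> set[tuple[int, int]]:
    """All cells a segment passes through, in fractional grid coordinates
    (u = column axis, v = row axis).  Amanatides-Woo traversal."""
    cells: set[tuple[int, int]] = set()
    x, y = math.floor(u0), math.floor(v0)
    xe, ye = math.floor(u1), math.floor(v1)
    dx, dy = u1 - u0, v1 - v0
    step_x = 1 if dx > 0 else -1
    step_y = 1 if dy > 0 else -1
    t_max_x = ((x + (step_x > 0)) - u0) / dx if dx != 0 else math.inf
    t_max_y = ((y + (step_y > 0)) - v0) / dy if dy != 0 else math.inf
    t_dx = abs(1.0 / dx) if dx != 0 else math.inf
    t_dy = abs(1.0 / dy) if dy != 0 else math.inf
    for _ in range(4 * (nrows + ncols) + 8):
        if 0 <= y < nrows and 0 <= x < ncols:
            cells.add((y, x))
        if x == xe and y == ye:
            break
        if t_max_x < t_max_y:
            x += step_x
            t_max_x += t_dx
        else:
            y += step_y
            t_max_y += t_dy
    return cells


def _line_coords(geom: BaseGeometry) -> Iterable[Sequence[tuple[float, float]]]:
    if geom.geom_type == "LineString":
        yield list(geom.coords)
    elif geom.geom_type == "MultiLineString":
        for part in geom.geoms:
            yield list(part.coords)
    else:
        raise ValueError(f"not a line geometry: {geom.geom_type}")


def rasterize_lines(geoms: Iterable[BaseGeometry], template: Grid) -> np.ndarray:
    """Boolean mask of every cell touched by any line (all-touched rule,
    so thin diagonal lines stay 8-connected at coarse resolutions)."""
    mask = np.zeros(template.shape, dtype=bool)
    cs = template.cell_size
    for geom in geoms:
        for coords in _line_coords(geom):
            for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
                u0 = (x0 - template.origin_x) / cs
                v0 = (template.origin_y - y0) / cs
                u1 = (x1 - template.origin_x) / cs
                v1 = (template.origin_y - y1) / cs
                for r, c in _segment_cells(u0, v0, u1, v1, *template.shape):
                    mask[r, c] = True
    return mask


def rasterize_polygons(geoms: Iterable[BaseGeometry], template: Grid) -> np.ndarray:
    """Boolean mask of cells whose center falls inside any polygon."""
    geoms = list(geoms)
    mask = np.zeros(template.shape, dtype=bool)
    if not geoms:
        return mask
    rows, cols = np.meshgrid(np.arange(template.nrows), np.arange(template.ncols),
                             indexing="ij")
    cx, cy = template.cell_center(rows.ravel(), cols.ravel())
    inside = np.zeros(cx.shape, dtype=bool)
    for geom in geoms:
        inside |= shapely.contains_xy(geom, cx, cy)
    return inside.reshape(template.shape)


def merge_cost_surface(landcover: Grid,
                       rivers: VectorLayer | None = None,
                       roads: VectorLayer | None = None,
                       water: VectorLayer | None = None,
                       road_class_attr: str = "class") -> Grid:
    """Merge landcover, water bodies, rivers and roads into one categorical
    friction surface.

    Precedence: landcover < water polygons < river lines < roads, so roads
    crossing rivers remain traversable (bridges).  Within the road layer,
    rural < district < national, which makes the result independent of
    feature order.
    """
    if landcover.kind != "categorical":
        raise ValueError("landcover must be a categorical grid")
    out = landcover.values.astype(np.int64, copy=True)

    if water is not None and len(water):
        out[rasterize_polygons(water.geometries(), landcover)] = WATER_CODE
    if rivers is not None and len(rivers):
        out[rasterize_lines(rivers.geometries(), landcover)] = WATER_CODE
    if roads is not None and len(roads):
        by_class: dict[str, list[BaseGeometry]] = {k: [] for k in ROAD_CODES}
        for geom, attrs in roads.features:
            rc = attrs.get(road_class_attr)
            if rc in ("rural_feeder", "feeder"):
                rc = "rural"
            if rc not in ROAD_CODES:
                raise ValueError(f"road feature with unknown class {rc!r}")
            by_class[rc].append(geom)
        for rc in ("rural", "district", "national"):  # slowest first
            if by_class[rc]:
                out[rasterize_lines(by_class[rc], landcover)] = ROAD_CODES[rc]
    merged = landcover.like(out, kind="categorical")
    return merged


# ---------------------------------------------------------------------------
# Facility cleaning
# ---------------------------------------------------------------------------

def _missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    if isinstance(v, str) and v.strip() == "":
        return True
    return False


def nearest_traversable_cell(cost_surface: Grid, row: int, col: int,
                             barrier_codes: set[int] | None = None
                             ) -> tuple[int, int]:
    """Nearest non-barrier, non-nodata cell by Euclidean center distance;
    ties broken by ascending (row, col)."""
    if barrier_codes is None:
        barrier_codes = {WATER_CODE}
    vals = cost_surface.values
    traversable = cost_surface.valid_mask & ~np.isin(vals, list(barrier_codes))
    if not traversable.any():
        raise ValueError("cost surface has no traversable cell")
    rr, cc = np.nonzero(traversable)
    d2 = (rr - row) ** 2 + (cc - col) ** 2
    order = np.lexsort((cc, rr, d2))  # distance, then row, then col
    i = order[0]
    return int(rr[i]), int(cc[i])


def clean_facilities(raw: pd.DataFrame, cost_surface: Grid,
                     barrier_codes: set[int] | None = None
                     ) -> tuple[list[Facility], FacilityCleanReport]:
    """Apply the facility inclusion rules and relocate barrier-sitting
    facilities.

    Rows missing coordinates and/or capacity are excluded and tallied by
    missingness pattern.  Included facilities that land on a water cell are
    moved to the nearest traversable cell (automating what was a manual
    step), with ties broken deterministically by (row, col).
    """
    if barrier_codes is None:
        barrier_codes = {WATER_CODE}
    required = {"id", "x", "y", "capacity"}
    if not required.issubset(raw.columns):
        raise ValueError(f"facility table must have columns {sorted(required)}")
    ids = raw["id"].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"duplicate facility id {dup!r}")

    n_total = len(raw)
    n_both = n_coords = n_cap = 0
    included: list[Facility] = []
    n_relocated = 0
    for _, rec in raw.iterrows():
        miss_xy = _missing(rec["x"]) or _missing(rec["y"])
        miss_cap = _missing(rec["capacity"])
        if miss_xy and miss_cap:
            n_both += 1
            continue
        if miss_xy:
            n_coords += 1
            continue
        if miss_cap:
            n_cap += 1
            continue
        x, y = float(rec["x"]), float(rec["y"])
        capacity = float(rec["capacity"])
        if capacity <= 0:
            raise ValueError(f"facility {rec['id']!r} has capacity <= 0")
        row, col = cost_surface.index_of(x, y)
        row, col = int(row), int(col)
        on_barrier = (
            not cost_surface.contains_index(row, col)
            or int(cost_surface.values[row, col]) in barrier_codes
            or not bool(cost_surface.valid_mask[row, col])
        )
        relocated = False
        if on_barrier:
            row, col = nearest_traversable_cell(cost_surface, row, col, barrier_codes)
            x, y = (float(v) for v in cost_surface.cell_center(row, col))
            relocated = True
            n_relocated += 1
        included.append(Facility(
            id=str(rec["id"]), x=x, y=y, capacity=capacity,
            ftype=str(rec.get("type", "health_centre")),
            row=row, col=col, relocated=relocated,
        ))
    report = FacilityCleanReport(
        n_total=n_total,
        n_missing_both=n_both,
        n_missing_coords_only=n_coords,
        n_missing_capacity_only=n_cap,
        n_included=len(included),
        n_relocated=n_relocated,
    )
    return included, report
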