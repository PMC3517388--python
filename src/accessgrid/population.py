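"""Dasymetric population mapping.

Sector-level population totals (third-level administrative units) are
redistributed onto the 90 m grid using per-landcover relative density
weights.  The weights come from *empirical sampling*: sectors wholly
occupied by a single inhabited landcover class yield that class's
population density directly; classes never observed alone fall back to a
configurable default.  Water bodies, rivers and roads form an exclusion
set that carries exactly zero population.

Each cell belongs to the sector containing its center, which keeps the
grid a partition of the study area and makes mass conservation exact: the
sum of the output grid equals the sum of the sector totals to machine
precision (pycnophylactic property).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .grids import Grid, VectorLayer
from .landscape import ROAD_CODES, WATER_CODE

__all__ = [
    "Sector",
    "DensityFractions",
    "DEFAULT_EXCLUDED_CLASSES",
    "sector_membership",
    "estimate_density_fractions",
    "dasymetric_redistribute",
]

#: Classes carrying zero population: water bodies plus the three road classes.
DEFAULT_EXCLUDED_CLASSES = frozenset({WATER_CODE} | set(ROAD_CODES.values()))


@dataclass(frozen=True)
class Sector:
    id: str
    geometry: BaseGeometry
    population: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.population) or self.population < 0:
            raise ValueError(f"sector {self.id!r} has invalid population")


@dataclass(frozen=True)
class DensityFractions:
    """Relative density weight per inhabited class (max weight = 1) and the
    zero-population exclusion set."""

    weights: Mapping[int, float]
    excluded: frozenset[int] = DEFAULT_EXCLUDED_CLASSES
    densities: Mapping[int, float] = field(default_factory=dict)  # persons/km^2

    def __post_init__(self) -> None:
        if not any(w > 0 for w in self.weights.values()):
            raise ValueError("at least one inhabited class needs positive weight")
        if any(c in self.weights and self.weights[c] != 0 for c in self.excluded):
            raise ValueError("excluded classes must have zero weight")

    def weight_of(self, code: int) -> float:
        if code in self.excluded:
            return 0.0
        return float(self.weights.get(code, 0.0))

    def as_dict(self) -> dict:
        return {
            "weights": {int(c): float(w) for c, w in sorted(self.weights.items())},
            "excluded": sorted(int(c) for c in self.excluded),
            "densities_per_km2": {int(c): float(d)
                                  for c, d in sorted(self.densities.items())},
        }


def _as_sectors(sectors) -> list[Sector]:
    if isinstance(sectors, VectorLayer):
        return [Sector(str(attrs["id"]), geom, float(attrs["population"]))
                for geom, attrs in sectors.features]
    return list(sectors)


def sector_membership(sectors, landcover: Grid) -> np.ndarray:
    """Integer grid of sector indices (−1 where no sector contains the cell
    center)."""
    secs = _as_sectors(sectors)
    rows, cols = np.meshgrid(np.arange(landcover.nrows), np.arange(landcover.ncols),
                             indexing="ij")
    cx, cy = landcover.cell_center(rows.ravel(), cols.ravel())
    member = np.full(cx.shape, -1, dtype=np.int64)
    for i, sec in enumerate(secs):
        hit = shapely.contains_xy(sec.geometry, cx, cy)
        member[hit & (member == -1)] = i
    return member.reshape(landcover.shape)


def estimate_density_fractions(sectors, landcover: Grid,
                               excluded: Iterable[int] = DEFAULT_EXCLUDED_CLASSES,
                               fallback: str = "mean",
                               membership: np.ndarray | None = None,
                               ) -> DensityFractions:
    """Estimate per-class density weights by empirical sampling.

    A sector is *pure* when all of its non-excluded cells share one
    inhabited landcover class; its density is population divided by the
    area of those cells.  The weight of a class is the mean density over
    its pure sectors, rescaled so the largest weight is 1.  Inhabited
    classes never observed alone take the ``fallback`` weight: ``"mean"``
    (mean of the estimated weights) or ``"zero"``.
    """
    secs = _as_sectors(sectors)
    excluded = frozenset(int(c) for c in excluded)
    if membership is None:
        membership = sector_membership(secs, landcover)
    cell_km2 = (landcover.cell_size / 1000.0) ** 2

    samples: dict[int, list[float]] = {}
    for i, sec in enumerate(secs):
        cells = landcover.values[(membership == i) & landcover.valid_mask]
        inhabited = cells[~np.isin(cells, list(excluded))]
        if inhabited.size == 0:
            continue
        codes = np.unique(inhabited)
        if codes.size != 1:
            continue
        density = sec.population / (inhabited.size * cell_km2)
        samples.setdefault(int(codes[0]), []).append(density)

    if not samples:
        raise ValueError("no single-class sector found for any inhabited class")
    densities = {c: float(np.mean(v)) for c, v in samples.items()}

    present = np.unique(landcover.values[landcover.valid_mask])
    inhabited_present = [int(c) for c in present if int(c) not in excluded]
    mean_density = float(np.mean(list(densities.values())))
    full = {}
    for c in inhabited_present:
        if c in densities:
            full[c] = densities[c]
        elif fallback == "mean":
            full[c] = mean_density
        elif fallback == "zero":
            full[c] = 0.0
        else:
            raise ValueError(f"class {c} never occurs alone and no fallback set")
    top = max(full.values())
    if top <= 0:
        raise ValueError("all estimated densities are zero")
    weights = {c: d / top for c, d in full.items()}
    # audit trail keeps only empirically sampled densities, not fallbacks
    return DensityFractions(weights=weights, excluded=excluded,
                            densities=densities)


def dasymetric_redistribute(sectors, landcover: Grid,
                            fractions: DensityFractions,
                            membership: np.ndarray | None = None) -> Grid:
    """Redistribute sector totals onto the grid.

    Cell value = sector_population * w(cell) / sum of w over the sector's
    cells, with w(cell) the class weight (0 on excluded classes).  Cells
    outside every sector are nodata.  A sector whose population is
    positive but whose cells are all excluded is an error — its people
    would be unplaceable.
    """
    secs = _as_sectors(sectors)
    if membership is None:
        membership = sector_membership(secs, landcover)
    weights_lut = np.zeros(int(landcover.values.max()) + 2)
    for c, w in fractions.weights.items():
        if c <= landcover.values.max():
            weights_lut[int(c)] = fractions.weight_of(int(c))
    codes = np.clip(landcover.values, 0, len(weights_lut) - 1)
    w = np.where(landcover.valid_mask, weights_lut[codes], 0.0)

    out = np.zeros(landcover.shape, dtype=float)
    for i, sec in enumerate(secs):
        inside = membership == i
        wsum = w[inside].sum()
        if wsum <= 0:
            if sec.population > 0:
                raise ValueError(
                    f"sector {sec.id!r} has population {sec.population} but only "
                    "excluded cells; population is unplaceable"
                )
            continue
        out[inside] = sec.population * w[inside] / wsum

    nodata = -9999.0
    out = np.where(membership >= 0, out, nodata)
    return landcover.like(out, kind="continuous", nodata=nodata)
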