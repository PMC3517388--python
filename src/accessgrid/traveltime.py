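"""Anisotropic travel-time surfaces over the merged friction grid.

Travel time from every cell to the nearest facility is computed by
Dijkstra's algorithm on the 8-connected grid graph.  Patients move toward
the facility, so the slope entering each edge is taken in the direction of
that motion; walking speeds follow Tobler's hiking function rescaled so
the flat-surface speed equals the class base speed, cycling speeds solve a
constant-power balance (rolling + grade + aerodynamic resistance)
calibrated the same way and capped downhill, and motorized speeds ignore
slope.  Water is a barrier and times beyond the cap (default 60 minutes,
the one-hour access norm) are nodata.

Edge cost uses the half-cell harmonic rule: crossing from cell A to
neighbour B over distance d costs (d/2)·(1/v_A + 1/v_B), the standard
raster cost-distance convention that halves resolution bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .grids import Grid, GridAlignmentError
from .landscape import Facility, SpeedTable, default_speed_table

__all__ = [
    "TOBLER_DECAY",
    "TOBLER_OFFSET",
    "WALK_FALLBACK_SPEED",
    "TravelTimeSurface",
    "tobler_walking_speed",
    "cycling_speed",
    "effective_speed",
    "travel_time_from",
    "per_facility_travel_times",
    "accessibility_surface",
]

# Tobler hiking function: v(s) = 6 * exp(-3.5 * |s + 0.05|) km/h.  We keep
# the shape and rescale so v(0) equals the class base speed.
TOBLER_DECAY = 3.5
TOBLER_OFFSET = 0.05
_TOBLER_FLAT = np.exp(-TOBLER_DECAY * TOBLER_OFFSET)

#: Walking speed taken on motorized-road cells outside the transit mask.
WALK_FALLBACK_SPEED = 5.0

# Constant-power cycling model parameters: total mass (rider + bicycle +
# load), rolling-resistance coefficient, and the aerodynamic drag constant
# 0.5 * air density * CdA.
_CYCLE_MASS_KG = 90.0
_CYCLE_CRR = 0.008
_CYCLE_DRAG = 0.5 * 1.2 * 0.5  # kg/m
_G = 9.81


def tobler_walking_speed(base_kmh, slope):
    """Walking speed (km/h) at a given rise/run slope, normalized so the
    flat-surface speed equals ``base_kmh``."""
    s = np.asarray(slope, dtype=float)
    return np.asarray(base_kmh) * np.exp(
        -TOBLER_DECAY * np.abs(s + TOBLER_OFFSET)
    ) / _TOBLER_FLAT


@lru_cache(maxsize=16)
def _cycling_table(base_kmh: float, downhill_cap: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Tabulated constant-power cycling speed over slope, for interpolation.

    Power on the flat at the base speed is held constant over terrain:
    drag*v^3 + (Crr + s)*m*g*v = P0.  The unique positive root is the
    riding speed; downhill speeds are capped at ``downhill_cap`` times the
    base speed.
    """
    v0 = base_kmh / 3.6
    p0 = _CYCLE_DRAG * v0 ** 3 + _CYCLE_CRR * _CYCLE_MASS_KG * _G * v0
    vmax = downhill_cap * v0
    slopes = np.linspace(-3.0, 3.0, 2401)
    speeds = np.empty_like(slopes)
    for i, s in enumerate(slopes):
        if s == 0.0:
            speeds[i] = v0
            continue
        def f(v, s=s):
            return _CYCLE_DRAG * v ** 3 + (_CYCLE_CRR + s) * _CYCLE_MASS_KG * _G * v - p0
        hi = max(vmax * 2, v0 * 2, 40.0)
        if f(hi) < 0:
            # free-wheeling faster than the cap allows; the cap binds
            speeds[i] = vmax
        else:
            speeds[i] = brentq(f, 1e-9, hi, xtol=1e-10)
    speeds = np.minimum(speeds, vmax) * 3.6
    return slopes, speeds


def cycling_speed(base_kmh, slope, downhill_cap: float = 1.5):
    """Cycling speed (km/h) from the constant-power balance, flat speed
    calibrated to ``base_kmh``, downhill capped at ``downhill_cap`` x and
    floored from below by walking the bicycle.

    On steep climbs the constant-power speed drops under walking pace; a
    patient then dismounts and pushes, so the effective speed is never
    below the slope-corrected road walking speed.
    """
    slopes, speeds = _cycling_table(float(base_kmh), float(downhill_cap))
    s = np.clip(np.asarray(slope, dtype=float), slopes[0], slopes[-1])
    ride = np.interp(s, slopes, speeds)
    push = tobler_walking_speed(min(WALK_FALLBACK_SPEED, base_kmh), s)
    return np.maximum(ride, push)


def effective_speed(cell_class: int, scenario: int, slope: float,
                    table: SpeedTable | None = None,
                    cycling_downhill_cap: float = 1.5) -> float:
    """Slope-corrected speed (km/h) for one class/scenario.

    ``slope`` is rise over run in the patient's direction of motion
    (toward the facility).  Raises for barrier classes.
    """
    table = table or default_speed_table()
    base, mode = table.speed_for(cell_class, scenario)
    if base == 0.0:
        raise ValueError(f"class {cell_class} is a barrier in scenario {scenario}")
    if slope == 0.0:
        return float(base)
    if mode == "walk":
        return float(tobler_walking_speed(base, slope))
    if mode == "bicycle":
        return float(cycling_speed(base, slope, cycling_downhill_cap))
    return float(base)  # motorized: no slope correction


@dataclass
class TravelTimeSurface:
    """Minutes to the nearest origin facility, NaN-valued where
    unreachable or beyond the cap."""

    grid: Grid
    scenario: int
    origin_ids: tuple[str, ...]
    cap_minutes: float
    beyond_cap: np.ndarray = field(repr=False, default=None)  # type: ignore
    unreachable: np.ndarray = field(repr=False, default=None)  # type: ignore

    @property
    def minutes(self) -> np.ndarray:
        return self.grid.values

    def reachable_mask(self) -> np.ndarray:
        return np.isfinite(self.grid.values)


def _cell_speed_fields(cost: Grid, scenario: int, table: SpeedTable,
                       transit_mask: np.ndarray | None):
    """Per-cell base speed (km/h) and mode code (0 walk, 1 bicycle,
    2 motorized); speed 0 marks barriers/nodata."""
    mode_code = {"walk": 0, "bicycle": 1, "motorized": 2, None: 0}
    base = np.zeros(cost.shape, dtype=float)
    mode = np.zeros(cost.shape, dtype=np.int8)
    vals = cost.values
    valid = cost.valid_mask
    for code in np.unique(vals[valid]):
        speed, m = table.speed_for(int(code), scenario)
        sel = valid & (vals == code)
        base[sel] = speed
        mode[sel] = mode_code[m]
    if transit_mask is not None:
        off = (mode == 2) & ~np.asarray(transit_mask, dtype=bool)
        base[off] = WALK_FALLBACK_SPEED
        mode[off] = 0
    return base, mode


_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _edge_speeds(base, mode, slope, cycling_downhill_cap):
    v = np.where(mode == 2, base, 0.0)
    walk = mode == 0
    if walk.any():
        v = np.where(walk, tobler_walking_speed(base, slope), v)
    bike = mode == 1
    if bike.any():
        for b in np.unique(base[bike]):
            sel = bike & (base == b)
            v[sel] = cycling_speed(b, slope[sel], cycling_downhill_cap)
    return v


def _build_graph(cost: Grid, dem: Grid, scenario: int, table: SpeedTable,
                 transit_mask, cycling_downhill_cap) -> tuple[csr_matrix, np.ndarray]:
    nrows, ncols = cost.shape
    n = nrows * ncols
    base, mode = _cell_speed_fields(cost, scenario, table, transit_mask)
    traversable = base > 0
    elev = np.where(dem.valid_mask, dem.values.astype(float), 0.0)
    idx = np.arange(n).reshape(nrows, ncols)

    rows_i, cols_j, data = [], [], []
    for dr, dc in _OFFSETS:
        # A at [ra, ca] expands to neighbour B at [ra+dr, ca+dc]
        a_r = slice(max(0, -dr), nrows - max(0, dr))
        a_c = slice(max(0, -dc), ncols - max(0, dc))
        b_r = slice(max(0, dr), nrows + min(0, dr))
        b_c = slice(max(0, dc), ncols + min(0, dc))
        ok = traversable[a_r, a_c] & traversable[b_r, b_c]
        if not ok.any():
            continue
        d = cost.cell_size * (np.sqrt(2.0) if dr and dc else 1.0)
        # patient moves B -> A, so slope is rise toward A
        s = (elev[a_r, a_c][ok] - elev[b_r, b_c][ok]) / d
        v_a = _edge_speeds(base[a_r, a_c][ok], mode[a_r, a_c][ok], s,
                           cycling_downhill_cap)
        v_b = _edge_speeds(base[b_r, b_c][ok], mode[b_r, b_c][ok], s,
                           cycling_downhill_cap)
        # minutes = (d/2 in km) * (1/v_a + 1/v_b in h/km) * 60
        t = 0.03 * d * (1.0 / v_a + 1.0 / v_b)
        rows_i.append(idx[a_r, a_c][ok])
        cols_j.append(idx[b_r, b_c][ok])
        data.append(t)
    graph = csr_matrix(
        (np.concatenate(data), (np.concatenate(rows_i), np.concatenate(cols_j))),
        shape=(n, n),
    )
    return graph, traversable


def travel_time_from(origins: list[Facility], cost: Grid, dem: Grid,
                     scenario: int, cap_minutes: float = 60.0,
                     table: SpeedTable | None = None,
                     transit_mask: np.ndarray | None = None,
                     cycling_downhill_cap: float = 1.5) -> TravelTimeSurface:
    """Travel-time surface (minutes) from every cell to its nearest origin.

    The search runs outward from the facility cells over the directed
    8-connected grid graph; each edge's slope is evaluated in the
    patient's direction of motion, so uphill-toward-facility transects
    cost more than the return journey.  Cells beyond ``cap_minutes`` or
    cut off by barriers are NaN.
    """
    table = table or default_speed_table()
    cost.require_aligned(dem, "DEM")
    if not origins:
        raise ValueError("at least one origin facility is required")
    graph, traversable = _build_graph(cost, dem, scenario, table,
                                      transit_mask, cycling_downhill_cap)
    origin_nodes = _origin_nodes(origins, cost, traversable)
    dist = dijkstra(graph, directed=True, indices=origin_nodes, min_only=True)
    return _surface_from_dist(dist, cost, traversable, scenario,
                              tuple(f.id for f in origins), cap_minutes)


def per_facility_travel_times(facilities: list[Facility], cost: Grid,
                              dem: Grid, scenario: int,
                              cap_minutes: float = 60.0,
                              table: SpeedTable | None = None,
                              transit_mask: np.ndarray | None = None,
                              cycling_downhill_cap: float = 1.5
                              ) -> dict[str, TravelTimeSurface]:
    """One travel-time surface per facility, sharing a single grid graph.

    Equivalent to calling :func:`travel_time_from` once per facility but
    the (expensive) edge construction happens only once per scenario.
    """
    table = table or default_speed_table()
    cost.require_aligned(dem, "DEM")
    if not facilities:
        raise ValueError("at least one facility is required")
    graph, traversable = _build_graph(cost, dem, scenario, table,
                                      transit_mask, cycling_downhill_cap)
    nodes = _origin_nodes(facilities, cost, traversable)
    out = {}
    for f, node in zip(facilities, nodes):
        dist = dijkstra(graph, directed=True, indices=[node], min_only=True)
        out[f.id] = _surface_from_dist(dist, cost, traversable, scenario,
                                       (f.id,), cap_minutes)
    return out


def _origin_nodes(origins, cost: Grid, traversable: np.ndarray) -> list[int]:
    nrows, ncols = cost.shape
    nodes = []
    for f in origins:
        if not (0 <= f.row < nrows and 0 <= f.col < ncols):
            raise ValueError(f"facility {f.id!r} lies outside the grid")
        if not traversable[f.row, f.col]:
            raise ValueError(f"facility {f.id!r} sits on a barrier cell")
        nodes.append(f.row * ncols + f.col)
    return nodes


def _surface_from_dist(dist: np.ndarray, cost: Grid, traversable: np.ndarray,
                       scenario: int, origin_ids: tuple[str, ...],
                       cap_minutes: float) -> TravelTimeSurface:
    minutes = dist.reshape(cost.shape)
    unreachable = ~np.isfinite(minutes) | ~traversable
    beyond = np.isfinite(minutes) & (minutes > cap_minutes)
    out = minutes.copy()
    out[unreachable | beyond] = np.nan
    grid = cost.like(out, kind="continuous", nodata=-9999.0)
    return TravelTimeSurface(
        grid=grid, scenario=scenario, origin_ids=origin_ids,
        cap_minutes=cap_minutes, beyond_cap=beyond, unreachable=unreachable,
    )


def accessibility_surface(surfaces: list[TravelTimeSurface]) -> TravelTimeSurface:
    """Cellwise minimum over per-facility surfaces (time to nearest
    facility); nodata only where every input is nodata."""
    if not surfaces:
        raise ValueError("no surfaces to combine")
    first = surfaces[0]
    for s in surfaces[1:]:
        if s.scenario != first.scenario:
            raise ValueError("surfaces mix scenarios")
        first.grid.require_aligned(s.grid, "travel-time surface")
    stack = np.stack([s.minutes for s in surfaces])
    filled = np.where(np.isfinite(stack), stack, np.inf)
    combined = filled.min(axis=0)
    combined[~np.isfinite(combined)] = np.nan
    beyond = np.all(np.stack([s.beyond_cap for s in surfaces]), axis=0) & \
        ~np.isfinite(combined)
    unreach = np.all(np.stack([s.unreachable for s in surfaces]), axis=0)
    ids = tuple(i for s in surfaces for i in s.origin_ids)
    return TravelTimeSurface(
        grid=first.grid.like(combined, kind="continuous", nodata=-9999.0),
        scenario=first.scenario, origin_ids=ids,
        cap_minutes=first.cap_minutes, beyond_cap=beyond, unreachable=unreach,
    )
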