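"""Seeded generator of complete synthetic input bundles.

The generator emulates the structure of the mountainous-rural study
landscape the pipeline assumes, so every stage is testable without any
download: a smoothed random-field DEM, a contiguous Voronoi tessellation
of sectors with known populations, landcover patches over the 13 generic
classes, connected road trees in three classes, rivers crossing the
domain, one lake acting as a barrier, and a facility table with
capacities, injected missingness and deliberate on-water placements to
exercise the cleaning rules.

Defaults mirror the study conditions: a provincial total population of
2,091,065 over 97 sectors, 113 facilities of which 9 lack both
coordinates and capacity, 7 lack coordinates only, 3 lack capacity only,
and 3 sit on water cells.  Sector populations are drawn from known
per-class density weights (with small multiplicative noise) so the
density-fraction estimator can be scored against ground truth; the sum is
forced to the configured total exactly, enabling machine-exact
conservation checks downstream.

One seed drives everything through deterministic per-layer substreams;
identical configurations produce byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Point, box
from shapely.ops import unary_union

from .grids import Grid, VectorLayer, write_grid, write_vector
from .landscape import ROAD_CODES, WATER_CODE, merge_cost_surface

__all__ = ["SynthConfig", "Bundle", "generate", "ground_truth"]

# Mixture over the 12 inhabited landcover classes (water enters via the
# lake and rivers): mostly cultivated and cropland mosaics, as in a
# densely farmed mountainous province.
_DEFAULT_MIXTURE = {
    9: 0.45, 1: 0.15, 7: 0.08, 2: 0.06, 13: 0.06, 4: 0.04,
    5: 0.04, 10: 0.04, 8: 0.03, 12: 0.02, 3: 0.015, 6: 0.015,
}

# True relative population densities (persons/km^2) per inhabited class
# used to synthesize sector populations; built-up land densest, flooded
# shrubland sparsest.
_DEFAULT_DENSITIES = {
    6: 1500.0, 9: 400.0, 1: 350.0, 7: 300.0, 13: 250.0, 2: 150.0,
    4: 100.0, 5: 80.0, 8: 60.0, 10: 60.0, 12: 40.0, 3: 20.0,
}


@dataclass
class SynthConfig:
    seed: int = 0
    nrows: int = 150
    ncols: int = 150
    cell_size: float = 90.0
    origin_x: float = 0.0
    origin_y: float | None = None  # default: nrows * cell_size
    # terrain: base elevation plus relief amplitude, smoothed at a
    # correlation length given in cells
    base_elevation: float = 900.0
    relief_amplitude: float = 2100.0
    correlation_length: float = 8.0
    n_sectors: int = 97
    total_population: int = 2_091_065
    landcover_mixture: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIXTURE))
    class_densities: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_DENSITIES))
    n_landcover_patches: int = 250
    # sectors forced to a single landcover class, so empirical density
    # sampling always has pure sectors to work from (round-robin: the
    # default puts one behind each of the 12 inhabited classes)
    pure_sector_quota: int = 12
    density_noise_sd: float = 0.02
    n_road_waypoints: dict[str, int] = field(
        default_factory=lambda: {"national": 4, "district": 6, "rural": 14})
    river_count: int = 2
    lake_fraction: float = 0.04
    n_facilities: int = 113
    capacity_mean: float = 20_000.0
    capacity_dispersion: float = 0.4  # lognormal sigma
    missing_both_rate: float = 9 / 113
    missing_coords_rate: float = 7 / 113
    missing_capacity_rate: float = 3 / 113
    on_water_fraction: float = 3 / 113

    def __post_init__(self) -> None:
        if self.nrows < 20 or self.ncols < 20:
            raise ValueError("grid must be at least 20x20")
        if self.total_population <= 0:
            raise ValueError("total_population must be positive")
        if not (0 <= self.lake_fraction < 1):
            raise ValueError("lake_fraction must be in [0, 1)")
        for r in (self.missing_both_rate, self.missing_coords_rate,
                  self.missing_capacity_rate, self.on_water_fraction):
            if not (0 <= r <= 1):
                raise ValueError("rates must lie in [0, 1]")
        if self.origin_y is None:
            self.origin_y = self.nrows * self.cell_size
        s = sum(self.landcover_mixture.values())
        if not np.isclose(s, 1.0):
            self.landcover_mixture = {c: v / s
                                      for c, v in self.landcover_mixture.items()}


@dataclass
class Bundle:
    """In-memory synthetic input bundle plus its ground-truth record."""

    config: SynthConfig
    dem: Grid
    landcover: Grid          # landcover only (pre-merge)
    cost_surface: Grid       # merged landcover + water + rivers + roads
    sectors: VectorLayer
    roads: VectorLayer
    rivers: VectorLayer
    water: VectorLayer
    facilities: pd.DataFrame
    truth: dict
    token: str = "accessgrid-synthetic-bundle"

    def write(self, out_dir: str | Path) -> Path:
        """Write the bundle in the file formats the pipeline consumes."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_grid(self.dem, out / "dem.asc")
        write_grid(self.landcover, out / "landcover.asc")
        write_grid(self.cost_surface, out / "cost_surface.asc")
        write_vector(self.sectors, out / "sectors.geojson")
        write_vector(self.roads, out / "roads.geojson")
        write_vector(self.rivers, out / "rivers.geojson")
        write_vector(self.water, out / "water.geojson")
        fac = self.facilities.copy()
        fac.to_csv(out / "facilities.csv", index=False, float_format="%.6f")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, sort_keys=True, indent=1)
        return out


def _rng_for(seed: int, layer: int) -> np.random.Generator:
    # deterministic per-layer substream off the single global seed
    return np.random.default_rng(np.random.SeedSequence([int(seed), layer]))


def _make_dem(cfg: SynthConfig, rng: np.random.Generator) -> Grid:
    field_ = rng.standard_normal((cfg.nrows, cfg.ncols))
    smooth = gaussian_filter(field_, sigma=cfg.correlation_length, mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    z = cfg.base_elevation + (smooth - lo) / (hi - lo) * cfg.relief_amplitude
    return Grid(np.round(z, 2), origin_x=cfg.origin_x, origin_y=cfg.origin_y,
                cell_size=cfg.cell_size, nodata=-9999.0, kind="continuous")


def _nearest_seed_labels(cfg: SynthConfig, seeds_rc: np.ndarray) -> np.ndarray:
    rows, cols = np.meshgrid(np.arange(cfg.nrows), np.arange(cfg.ncols),
                             indexing="ij")
    pts = np.stack([rows.ravel(), cols.ravel()], axis=1)
    from scipy.spatial import cKDTree

    tree = cKDTree(seeds_rc)
    _, lab = tree.query(pts)
    return lab.reshape(cfg.nrows, cfg.ncols)


def _make_sectors(cfg: SynthConfig, rng: np.random.Generator,
                  template: Grid) -> tuple[np.ndarray, list[shapely.Geometry]]:
    """Grid Voronoi tessellation: each cell joins its nearest sector seed;
    sector polygons are exact unions of their cell squares."""
    seeds = rng.uniform([0, 0], [cfg.nrows, cfg.ncols], size=(cfg.n_sectors, 2))
    labels = _nearest_seed_labels(cfg, seeds)
    cs = template.cell_size
    polys = []
    for i in range(cfg.n_sectors):
        rr, cc = np.nonzero(labels == i)
        boxes = [
            box(template.origin_x + c * cs, template.origin_y - (r + 1) * cs,
                template.origin_x + (c + 1) * cs, template.origin_y - r * cs)
            for r, c in zip(rr, cc)
        ]
        polys.append(unary_union(boxes))
    return labels, polys


def _make_landcover(cfg: SynthConfig, rng: np.random.Generator,
                    template: Grid, sector_labels: np.ndarray) -> Grid:
    codes = np.array(sorted(cfg.landcover_mixture))
    probs = np.array([cfg.landcover_mixture[c] for c in codes])
    probs = probs / probs.sum()
    n_patch = max(cfg.n_landcover_patches, len(codes))
    patch_rc = rng.uniform([0, 0], [cfg.nrows, cfg.ncols], size=(n_patch, 2))
    patch_class = rng.choice(codes, size=n_patch, p=probs)
    labels = _nearest_seed_labels(cfg, patch_rc)
    lc = patch_class[labels]
    if cfg.pure_sector_quota > 0:
        # force whole sectors to a single class so empirical sampling of
        # densities always has pure sectors to work from
        n_q = min(cfg.pure_sector_quota, cfg.n_sectors)
        chosen = rng.choice(cfg.n_sectors, size=n_q, replace=False)
        # round-robin over the classes so a quota of 3 * n_classes puts
        # at least 3 pure sectors behind every inhabited class
        pure_classes = np.array([codes[k % len(codes)] for k in range(n_q)])
        for sec, cls in zip(chosen, pure_classes):
            lc[sector_labels == sec] = cls
    return template.like(lc.astype(np.int64), kind="categorical", nodata=-1)


def _make_lake(cfg: SynthConfig, rng: np.random.Generator,
               template: Grid) -> VectorLayer:
    if cfg.lake_fraction <= 0:
        return VectorLayer("polygon", [])
    area = cfg.lake_fraction * cfg.nrows * cfg.ncols * template.cell_size ** 2
    radius = np.sqrt(area / np.pi)
    # keep the lake near the western edge, like a border lake
    cx = template.origin_x + 0.18 * cfg.ncols * template.cell_size
    cy = template.origin_y - (0.3 + 0.4 * rng.random()) * cfg.nrows * template.cell_size
    lake = Point(cx, cy).buffer(radius, quad_segs=24)
    return VectorLayer("polygon", [(lake, {"name": "lake"})])


def _make_rivers(cfg: SynthConfig, rng: np.random.Generator,
                 template: Grid) -> VectorLayer:
    feats = []
    w = cfg.ncols * template.cell_size
    h = cfg.nrows * template.cell_size
    for k in range(cfg.river_count):
        x = template.origin_x + (0.25 + 0.5 * rng.random()) * w
        pts = []
        n_seg = 12
        for i in range(n_seg + 1):
            y = template.origin_y - h * i / n_seg
            jitter = (rng.random() - 0.5) * 0.12 * w
            pts.append((x + jitter, y))
        feats.append((LineString(pts), {"name": f"river_{k}"}))
    return VectorLayer("line", feats)


def _make_roads(cfg: SynthConfig, rng: np.random.Generator,
                template: Grid) -> VectorLayer:
    """Per class, a Euclidean minimum spanning tree over random waypoints:
    connected by construction, and still connected after all-touched
    rasterization."""
    from scipy.sparse.csgraph import minimum_spanning_tree
    from scipy.spatial.distance import squareform, pdist

    feats = []
    w = cfg.ncols * template.cell_size
    h = cfg.nrows * template.cell_size
    for cls, n_wp in cfg.n_road_waypoints.items():
        if n_wp < 2:
            continue
        xy = np.column_stack([
            template.origin_x + rng.uniform(0.05, 0.95, n_wp) * w,
            template.origin_y - rng.uniform(0.05, 0.95, n_wp) * h,
        ])
        dist = squareform(pdist(xy))
        mst = minimum_spanning_tree(dist).tocoo()
        for i, j in zip(mst.row, mst.col):
            feats.append((LineString([xy[i], xy[j]]), {"class": cls}))
    return VectorLayer("line", feats)


def _sector_populations(cfg: SynthConfig, rng: np.random.Generator,
                        cost: Grid, sector_labels: np.ndarray) -> np.ndarray:
    """Populations consistent with the per-class density truth, scaled to
    the configured total exactly (largest-remainder rounding)."""
    cell_km2 = (cfg.cell_size / 1000.0) ** 2
    dens = np.zeros(int(cost.values.max()) + 1)
    for c, d in cfg.class_densities.items():
        dens[c] = d
    raw = np.zeros(cfg.n_sectors)
    vals = cost.values
    for i in range(cfg.n_sectors):
        cells = vals[sector_labels == i]
        raw[i] = dens[cells].sum() * cell_km2
    noise = np.exp(rng.normal(0.0, cfg.density_noise_sd, cfg.n_sectors))
    raw = raw * noise
    placeable = raw > 0
    if not placeable.any():
        raise ValueError("no sector can hold population (infeasible config)")
    scaled = np.where(placeable, raw / raw.sum() * cfg.total_population, 0.0)
    pops = np.floor(scaled).astype(np.int64)
    deficit = int(cfg.total_population - pops.sum())
    remainders = np.where(placeable, scaled - np.floor(scaled), -np.inf)
    order = np.argsort(-remainders, kind="stable")
    n_placeable = int(placeable.sum())
    for k in range(deficit):
        pops[order[k % n_placeable]] += 1
    return pops


def _make_facilities(cfg: SynthConfig, rng: np.random.Generator,
                     cost: Grid, pop_weight: np.ndarray
                     ) -> tuple[pd.DataFrame, dict]:
    n = cfg.n_facilities
    vals = cost.values
    land = vals != WATER_CODE
    water_cells = np.column_stack(np.nonzero(~land))
    p = np.where(land, pop_weight, 0.0).ravel()
    p = p / p.sum()
    flat = rng.choice(vals.size, size=n, replace=False, p=p)
    rows, cols = np.unravel_index(flat, vals.shape)
    x, y = cost.cell_center(rows, cols)
    x, y = np.asarray(x, float), np.asarray(y, float)

    n_water = int(round(cfg.on_water_fraction * n))
    n_both = int(round(cfg.missing_both_rate * n))
    n_xy = int(round(cfg.missing_coords_rate * n))
    n_cap = int(round(cfg.missing_capacity_rate * n))
    if n_both + n_xy + n_cap + n_water > n:
        raise ValueError("missingness and on-water counts exceed n_facilities")
    perm = rng.permutation(n)
    idx_both = perm[:n_both]
    idx_xy = perm[n_both:n_both + n_xy]
    idx_cap = perm[n_both + n_xy:n_both + n_xy + n_cap]
    idx_wet = perm[n_both + n_xy + n_cap:n_both + n_xy + n_cap + n_water]
    if n_water and len(water_cells):
        wet = water_cells[rng.choice(len(water_cells), size=n_water, replace=False)]
        wx, wy = cost.cell_center(wet[:, 0], wet[:, 1])
        x[idx_wet], y[idx_wet] = np.asarray(wx, float), np.asarray(wy, float)

    capacity = np.round(
        cfg.capacity_mean * np.exp(
            rng.normal(-cfg.capacity_dispersion ** 2 / 2,
                       cfg.capacity_dispersion, n))
    )
    ftype = rng.choice(["health_centre", "health_post", "dispensary"],
                       size=n, p=[0.85, 0.05, 0.10])
    df = pd.DataFrame({
        "id": [f"F{k + 1:03d}" for k in range(n)],
        "x": x, "y": y,
        "capacity": capacity.astype(float),
        "type": ftype,
    })
    df.loc[np.concatenate([idx_both, idx_xy]), ["x", "y"]] = np.nan
    df.loc[np.concatenate([idx_both, idx_cap]), "capacity"] = np.nan
    truth = {
        "n_missing_both": n_both,
        "n_missing_coords_only": n_xy,
        "n_missing_capacity_only": n_cap,
        "n_on_water": int(n_water),
        "on_water_ids": sorted(df["id"].iloc[idx_wet].tolist()),
    }
    return df, truth


def generate(config: SynthConfig) -> Bundle:
    """Generate a complete, internally consistent synthetic input bundle.

    Identical configurations (same seed) produce identical bundles; see
    :meth:`Bundle.write` for the on-disk form.
    """
    cfg = config
    dem = _make_dem(cfg, _rng_for(cfg.seed, 1))
    sector_labels, sector_polys = _make_sectors(cfg, _rng_for(cfg.seed, 2), dem)
    landcover = _make_landcover(cfg, _rng_for(cfg.seed, 3), dem, sector_labels)
    water = _make_lake(cfg, _rng_for(cfg.seed, 4), dem)
    rivers = _make_rivers(cfg, _rng_for(cfg.seed, 5), dem)
    roads = _make_roads(cfg, _rng_for(cfg.seed, 6), dem)
    cost = merge_cost_surface(landcover, rivers=rivers, roads=roads, water=water)

    pops = _sector_populations(cfg, _rng_for(cfg.seed, 7), cost, sector_labels)
    # a sector fully swallowed by water/roads could hold nobody; give it 0
    for i in range(cfg.n_sectors):
        cells = cost.values[sector_labels == i]
        from .population import DEFAULT_EXCLUDED_CLASSES

        if np.isin(cells, list(DEFAULT_EXCLUDED_CLASSES)).all() and pops[i] > 0:
            spill = pops[i]
            pops[i] = 0
            j = int(np.argmax(pops))
            pops[j] += spill
    sectors = VectorLayer("polygon", [
        (poly, {"id": f"S{i + 1:03d}", "population": int(pops[i])})
        for i, poly in enumerate(sector_polys)
    ])

    # population weight field for placing facilities near people
    cell_w = np.zeros(cfg.nrows * cfg.ncols)
    dens = np.zeros(int(cost.values.max()) + 1)
    for c, d in cfg.class_densities.items():
        dens[c] = d
    cell_w = dens[cost.values].ravel() + 1e-9
    facilities, fac_truth = _make_facilities(
        cfg, _rng_for(cfg.seed, 8), cost, cell_w.reshape(cost.shape))

    top = max(cfg.class_densities.values())
    truth = {
        "seed": cfg.seed,
        "total_population": int(cfg.total_population),
        "sector_populations": {f"S{i + 1:03d}": int(pops[i])
                               for i in range(cfg.n_sectors)},
        "class_densities_per_km2": {str(c): float(d)
                                    for c, d in sorted(cfg.class_densities.items())},
        "class_weights": {str(c): float(d / top)
                          for c, d in sorted(cfg.class_densities.items())},
        "facilities": fac_truth,
        "capacities": {r.id: (None if np.isnan(r.capacity) else float(r.capacity))
                       for r in facilities.itertuples()},
    }
    return Bundle(config=cfg, dem=dem, landcover=landcover, cost_surface=cost,
                  sectors=sectors, roads=roads, rivers=rivers, water=water,
                  facilities=facilities, truth=truth)


def ground_truth(bundle: Bundle) -> dict:
    """The injected quantities of a bundle, for parameter-recovery tests."""
    if getattr(bundle, "token", None) != "accessgrid-synthetic-bundle":
        raise ValueError("not a bundle produced by generate()")
    return bundle.truth
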