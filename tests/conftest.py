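"""Shared fixtures: tiny hand-built grids and seeded synthetic bundles.

The bundle fleet is computed once per session: each bundle is generated,
cleaned, dasymetrically populated, and carried through travel time and
catchment allocation for all three scenarios, so the property tests can
assert different invariants on the same computed objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from accessgrid import (
    Facility,
    Grid,
    SynthConfig,
    allocate_catchments,
    accessibility_surface,
    clean_facilities,
    dasymetric_redistribute,
    estimate_density_fractions,
    generate,
    per_facility_travel_times,
    scenario_coverage,
)
from accessgrid.population import sector_membership

N_FLEET_BUNDLES = 20


def small_config(seed: int, **overrides) -> SynthConfig:
    """Down-scaled study landscape for full-pipeline tests.

    A 13.5 km domain with relief, facility spacing and capacities chosen
    so the walking scenario is predominantly travel-time-limited and
    coverage grows across scenarios — the regime the method is meant for
    (see docs/methods.md on scaling).
    """
    kw = dict(
        seed=seed, nrows=150, ncols=150, n_sectors=24, n_facilities=9,
        total_population=250_000, n_landcover_patches=450,
        relief_amplitude=700.0,
        n_road_waypoints={"national": 3, "district": 5, "rural": 24},
        pure_sector_quota=8, capacity_mean=40_000,
        missing_both_rate=1 / 9, missing_coords_rate=1 / 9,
        missing_capacity_rate=0.0, on_water_fraction=1 / 9,
    )
    kw.update(overrides)
    return SynthConfig(**kw)


def flat_world(n: int = 7, code: int = 9, cell: float = 90.0):
    """Flat DEM + single-class landcover, for closed-form time checks."""
    lc = Grid(np.full((n, n), code, dtype=np.int64), cell_size=cell,
              origin_y=n * cell, nodata=-1, kind="categorical")
    dem = Grid(np.zeros((n, n)), cell_size=cell, origin_y=n * cell,
               nodata=-9999.0, kind="continuous")
    return lc, dem


def facility_at(grid: Grid, row: int, col: int, capacity: float = 1e12,
                fid: str = "F") -> Facility:
    x, y = grid.cell_center(row, col)
    return Facility(fid, float(x), float(y), capacity, row=row, col=col)


@dataclass
class BundleRun:
    """A synthetic bundle carried through the whole analysis."""

    bundle: object
    facilities: list
    clean_report: object
    fractions: object
    population: Grid
    surfaces: dict          # scenario -> {facility id -> TravelTimeSurface}
    nearest: dict           # scenario -> combined TravelTimeSurface
    catchments: dict        # scenario -> list[CatchmentResult]
    coverage: dict          # scenario -> scenario_coverage dict


def run_bundle(seed: int) -> BundleRun:
    bundle = generate(small_config(seed))
    facilities, clean_report = clean_facilities(bundle.facilities,
                                                bundle.cost_surface)
    membership = sector_membership(bundle.sectors, bundle.cost_surface)
    fractions = estimate_density_fractions(bundle.sectors, bundle.cost_surface,
                                           membership=membership)
    population = dasymetric_redistribute(bundle.sectors, bundle.cost_surface,
                                         fractions, membership=membership)
    surfaces, nearest, catch, cov = {}, {}, {}, {}
    for s in (1, 2, 3):
        surfaces[s] = per_facility_travel_times(
            facilities, bundle.cost_surface, bundle.dem, s)
        nearest[s] = accessibility_surface(list(surfaces[s].values()))
        catch[s] = allocate_catchments(facilities, surfaces[s], population)
        cov[s] = scenario_coverage(catch[s], population,
                                   clean_report.n_included)
    return BundleRun(bundle=bundle, facilities=facilities,
                     clean_report=clean_report, fractions=fractions,
                     population=population, surfaces=surfaces,
                     nearest=nearest, catchments=catch, coverage=cov)


@pytest.fixture(scope="session")
def bundle_fleet() -> list[BundleRun]:
    return [run_bundle(seed) for seed in range(N_FLEET_BUNDLES)]


@pytest.fixture(scope="session")
def one_run(bundle_fleet) -> BundleRun:
    return bundle_fleet[0]
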