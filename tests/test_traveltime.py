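"""Slope-corrected speeds and least-cost travel-time surfaces."""

import math

import numpy as np
import pytest

from accessgrid import (Grid, accessibility_surface, cycling_speed,
                        effective_speed, per_facility_travel_times,
                        tobler_walking_speed, travel_time_from)
from accessgrid.landscape import LANDCOVER_CODES, WATER_CODE, default_speed_table
from tests.conftest import facility_at, flat_world


class TestEffectiveSpeed:
    def test_flat_speed_equals_base_for_every_walkable_class(self):
        table = default_speed_table()
        for code in sorted(table.known_codes()):
            for scenario in (1, 2, 3):
                base, mode = table.speed_for(code, scenario)
                if base == 0.0:
                    with pytest.raises(ValueError, match="barrier"):
                        effective_speed(code, scenario, 0.0)
                else:
                    assert effective_speed(code, scenario, 0.0) == base

    def test_tobler_walking_at_ten_percent_uphill(self):
        # normalized Tobler: 5 * exp(-3.5*|0.10 + 0.05|) / exp(-0.175)
        expected = 5.0 * math.exp(-0.35)
        assert effective_speed(14, 1, 0.10) == pytest.approx(expected, rel=1e-12)
        assert tobler_walking_speed(5.0, 0.10) == pytest.approx(expected)

    def test_tobler_fastest_slightly_downhill(self):
        s = np.linspace(-0.5, 0.5, 1001)
        v = tobler_walking_speed(5.0, s)
        assert s[np.argmax(v)] == pytest.approx(-0.05, abs=1e-3)

    def test_motorized_ignores_slope(self):
        for slope in (-0.3, 0.0, 0.4):
            assert effective_speed(14, 3, slope) == 50.0

    def test_cycling_flat_calibration_and_downhill_cap(self):
        assert cycling_speed(10.0, 0.0) == pytest.approx(10.0)
        assert cycling_speed(10.0, -1.0) == pytest.approx(15.0)  # 1.5x cap
        assert cycling_speed(10.0, 0.02) < 10.0

    def test_cycling_never_slower_than_pushing_the_bike(self):
        # on steep climbs the rider dismounts: floor at road walking speed
        s = np.linspace(0.0, 0.5, 101)
        assert np.all(cycling_speed(10.0, s) >= tobler_walking_speed(5.0, s) - 1e-12)

    def test_positive_everywhere(self):
        s = np.linspace(-2, 2, 401)
        assert np.all(cycling_speed(10.0, s) > 0)
        assert np.all(tobler_walking_speed(1.0, s) > 0)


class TestTravelTimeSurface:
    def test_facility_cell_is_zero_and_axial_neighbor_closed_form(self):
        lc, dem = flat_world(5, code=6)  # built-up: 5 km/h walking
        f = facility_at(lc, 2, 2)
        surf = travel_time_from([f], lc, dem, 1)
        assert surf.minutes[2, 2] == 0.0
        # 90 m at 5 km/h: 0.09 / 5 * 60 = 1.08 min
        assert surf.minutes[2, 3] == pytest.approx(1.08)
        assert surf.minutes[1, 2] == pytest.approx(1.08)
        assert surf.minutes[1, 1] == pytest.approx(1.08 * math.sqrt(2))

    def test_flat_terrain_isotropy(self):
        lc, dem = flat_world(9)
        f = facility_at(lc, 4, 4)
        t = travel_time_from([f], lc, dem, 1).minutes
        # all cells at equal grid-path distance agree to ~1e-9 minutes
        assert abs(t[4, 0] - t[0, 4]) < 1e-9
        assert abs(t[0, 0] - t[8, 8]) < 1e-9
        assert abs(t[2, 6] - t[6, 2]) < 1e-9

    def test_slope_asymmetry_on_a_transect(self):
        """Walking to a hilltop facility takes longer than walking to a
        valley one over the same transect."""
        n = 7
        lc, _ = flat_world(n)
        ramp = np.tile(np.arange(n) * 20.0, (n, 1))  # rises eastward
        dem = lc.like(ramp, kind="continuous")
        top = facility_at(lc, 3, n - 1, fid="top")
        bottom = facility_at(lc, 3, 0, fid="bottom")
        t_top = travel_time_from([top], lc, dem, 1).minutes
        t_bottom = travel_time_from([bottom], lc, dem, 1).minutes
        # same transect, same endpoints: uphill-toward-facility is slower
        assert t_top[3, 0] > t_bottom[3, n - 1]

    def test_water_wall_blocks_and_is_nodata(self):
        lc, dem = flat_world(7)
        lc.values[:, 3] = WATER_CODE
        f = facility_at(lc, 3, 1)
        surf = travel_time_from([f], lc, dem, 1)
        assert np.all(np.isnan(surf.minutes[:, 3]))   # barrier itself
        assert np.all(np.isnan(surf.minutes[:, 4:]))  # cut-off far side
        assert np.all(np.isfinite(surf.minutes[:, :3]))

    def test_cap_truncates_to_nodata(self):
        lc, dem = flat_world(9, code=3)  # 1 km/h: 90 m cell = 5.4 min
        f = facility_at(lc, 0, 0)
        surf = travel_time_from([f], lc, dem, 1, cap_minutes=12.0)
        assert np.isfinite(surf.minutes[0, 2])   # 10.8 min
        assert np.isnan(surf.minutes[0, 3])      # 16.2 min > cap
        assert surf.beyond_cap[0, 3] and not surf.unreachable[0, 3]

    def test_unaligned_grids_rejected(self):
        lc, _ = flat_world(5)
        dem_wrong = Grid(np.zeros((5, 5)), cell_size=30)
        with pytest.raises(Exception, match="aligned"):
            travel_time_from([facility_at(lc, 2, 2)], lc, dem_wrong, 1)

    def test_origin_on_barrier_rejected(self):
        lc, dem = flat_world(5)
        lc.values[2, 2] = WATER_CODE
        with pytest.raises(ValueError, match="barrier"):
            travel_time_from([facility_at(lc, 2, 2)], lc, dem, 1)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_shortest_path_oracle(self, seed):
        """Grid Dijkstra equals a networkx shortest path over edges the
        test builds itself from the stated half-cell harmonic cost."""
        import networkx as nx

        rng = np.random.default_rng(seed)
        n = 7
        codes = rng.choice([1, 4, 9, 14, 16], size=(n, n))
        lc = Grid(codes.astype(np.int64), origin_y=n * 90.0, nodata=-1,
                  kind="categorical")
        dem = lc.like(rng.uniform(900, 1400, size=(n, n)).round(1),
                      kind="continuous")
        scenario = int(rng.integers(1, 4))
        f = facility_at(lc, int(rng.integers(n)), int(rng.integers(n)))
        surf = travel_time_from([f], lc, dem, scenario, cap_minutes=1e9)

        g = nx.DiGraph()
        for r in range(n):
            for c in range(n):
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = r + dr, c + dc
                        if (dr, dc) == (0, 0) or not (0 <= r2 < n and 0 <= c2 < n):
                            continue
                        d = 90.0 * math.hypot(dr, dc)
                        s = (dem.values[r, c] - dem.values[r2, c2]) / d
                        v_a = effective_speed(int(codes[r, c]), scenario, s)
                        v_b = effective_speed(int(codes[r2, c2]), scenario, s)
                        minutes = (d / 2000.0) * (1 / v_a + 1 / v_b) * 60.0
                        g.add_edge((r, c), (r2, c2), weight=minutes)
        oracle = nx.single_source_dijkstra_path_length(g, (f.row, f.col))
        for (r, c), t in oracle.items():
            assert surf.minutes[r, c] == pytest.approx(t, abs=1e-9)


class TestTransitMask:
    def test_motorized_speed_only_inside_mask(self):
        """Outside the transit mask, national-road cells are walked at
        5 km/h; inside, the minibus speed applies."""
        n = 5
        lc, dem = flat_world(n, code=14)  # all national road
        f = facility_at(lc, 2, 0)
        t_none = travel_time_from([f], lc, dem, 3, transit_mask=None).minutes
        empty_mask = np.zeros((n, n), dtype=bool)
        t_masked = travel_time_from([f], lc, dem, 3,
                                    transit_mask=empty_mask).minutes
        # 4 axial cells east: 360 m at 50 km/h vs at 5 km/h
        assert t_none[2, 4] == pytest.approx(0.36 / 50 * 60)
        assert t_masked[2, 4] == pytest.approx(0.36 / 5 * 60)
        full_mask = np.ones((n, n), dtype=bool)
        t_full = travel_time_from([f], lc, dem, 3,
                                  transit_mask=full_mask).minutes
        np.testing.assert_allclose(t_full, t_none)


class TestAccessibilitySurface:
    def test_single_surface_is_identity(self):
        lc, dem = flat_world(5)
        surf = travel_time_from([facility_at(lc, 2, 2)], lc, dem, 1)
        combo = accessibility_surface([surf])
        np.testing.assert_array_equal(combo.minutes, surf.minutes)

    def test_two_facilities_cellwise_minimum(self):
        lc, dem = flat_world(5)
        a = travel_time_from([facility_at(lc, 0, 0, fid="a")], lc, dem, 1)
        b = travel_time_from([facility_at(lc, 4, 4, fid="b")], lc, dem, 1)
        combo = accessibility_surface([a, b])
        for r in range(5):
            for c in range(5):
                assert combo.minutes[r, c] == min(a.minutes[r, c],
                                                  b.minutes[r, c])

    def test_adding_a_facility_never_increases_time(self):
        lc, dem = flat_world(6)
        a = travel_time_from([facility_at(lc, 0, 0, fid="a")], lc, dem, 1)
        b = travel_time_from([facility_at(lc, 5, 5, fid="b")], lc, dem, 1)
        combo = accessibility_surface([a, b]).minutes
        assert np.all(combo <= a.minutes + 1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            accessibility_surface([])


class TestScenarioMonotonicity:
    def test_faster_modes_never_slow_any_cell(self, one_run):
        """With identical terrain and origins, scenarios 2 and 3 dominate
        scenario 1 cell by cell."""
        t1 = one_run.nearest[1].minutes
        for s in (2, 3):
            ts = one_run.nearest[s].minutes
            have1 = np.isfinite(t1)
            assert np.all(np.isfinite(ts[have1]))
            assert np.all(ts[have1] <= t1[have1] + 1e-9)
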