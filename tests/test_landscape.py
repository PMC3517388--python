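"""Speed model, cost-surface merging and facility cleaning."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Polygon, box

from accessgrid import (Grid, VectorLayer, clean_facilities,
                        default_speed_table, merge_cost_surface, speed_for)
from accessgrid.landscape import LANDCOVER_CODES, ROAD_CODES, WATER_CODE


def categorical(values, cell=90.0):
    values = np.asarray(values, dtype=np.int64)
    return Grid(values, origin_y=values.shape[0] * cell, cell_size=cell,
                nodata=-1, kind="categorical")


class TestSpeedTable:
    @pytest.mark.parametrize("code,scenario,speed,mode", [
        (14, 3, 50.0, "motorized"),   # national road, public transport
        (15, 3, 20.0, "motorized"),   # district road
        (16, 3, 5.0, "walk"),         # rural/feeder: still on foot
        (16, 2, 10.0, "bicycle"),
        (14, 2, 10.0, "bicycle"),
        (14, 1, 5.0, "walk"),
        (9, 1, 1.67, "walk"),         # cultivated and managed areas
        (4, 1, 2.5, "walk"),          # sparse herbaceous or shrub
        (6, 1, 5.0, "walk"),          # artificial / built-up
        (3, 1, 1.0, "walk"),          # regularly flooded shrub
    ])
    def test_scenario_speeds(self, code, scenario, speed, mode):
        assert speed_for(code, scenario) == (speed, mode)

    @pytest.mark.parametrize("scenario", [1, 2, 3])
    def test_water_is_barrier_in_every_scenario(self, scenario):
        speed, mode = speed_for(WATER_CODE, scenario)
        assert speed == 0.0 and mode is None
        assert default_speed_table().is_barrier(WATER_CODE, scenario)

    def test_unknown_class_and_scenario(self):
        with pytest.raises(ValueError):
            speed_for(99, 1)
        with pytest.raises(ValueError):
            speed_for(9, 4)

    def test_scenario_dominance(self):
        """Adding a bicycle or a minibus never slows anyone down: base
        speeds of scenarios 2 and 3 dominate scenario 1 pointwise."""
        table = default_speed_table()
        for code in sorted(table.known_codes()):
            s1, _ = table.speed_for(code, 1)
            if s1 == 0:
                continue
            assert table.speed_for(code, 2)[0] >= s1
            assert table.speed_for(code, 3)[0] >= s1

    def test_off_road_classes_identical_across_scenarios(self):
        table = default_speed_table()
        for code in LANDCOVER_CODES:
            assert table.speed_for(code, 1) == table.speed_for(code, 2) \
                == table.speed_for(code, 3)


def _oracle_touched_cells(coords, template, n_samples=20000):
    """Independent all-touched oracle: dense sampling along the line."""
    touched = set()
    line = LineString(coords)
    for t in np.linspace(0, 1, n_samples):
        p = line.interpolate(t, normalized=True)
        r, c = template.index_of(p.x, p.y)
        if 0 <= r < template.nrows and 0 <= c < template.ncols:
            touched.add((int(r), int(c)))
    return touched


class TestMergeCostSurface:
    def test_no_vectors_is_identity(self):
        lc = categorical(np.full((5, 5), 9))
        out = merge_cost_surface(lc)
        np.testing.assert_array_equal(out.values, lc.values)

    def test_road_over_river_is_a_bridge(self):
        lc = categorical(np.full((5, 5), 9))
        # river runs along row 2, road along column 2; they cross at (2, 2)
        river = VectorLayer("line", [(LineString([(0, 225), (450, 225)]), {})])
        road = VectorLayer("line", [
            (LineString([(225, 0), (225, 450)]), {"class": "national"})])
        out = merge_cost_surface(lc, rivers=river, roads=road)
        assert out.values[2, 2] == ROAD_CODES["national"]
        assert out.values[2, 0] == WATER_CODE
        assert out.values[0, 2] == ROAD_CODES["national"]

    def test_water_polygon_becomes_barrier(self):
        lc = categorical(np.full((4, 4), 1))
        lake = VectorLayer("polygon", [(box(0, 0, 180, 180), {})])
        out = merge_cost_surface(lc, water=lake)
        assert (out.values == WATER_CODE).sum() == 4
        assert out.values[2, 0] == WATER_CODE  # SW corner cells

    def test_diagonal_road_matches_sampling_oracle(self):
        lc = categorical(np.full((5, 5), 9))
        coords = [(10, 15), (440, 430)]
        road = VectorLayer("line", [(LineString(coords), {"class": "rural"})])
        out = merge_cost_surface(lc, roads=road)
        got = {tuple(rc) for rc in
               np.argwhere(out.values == ROAD_CODES["rural"])}
        assert got == _oracle_touched_cells(coords, lc)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_polyline_matches_sampling_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lc = categorical(np.full((8, 8), 9))
        coords = [tuple(v) for v in rng.uniform(5, 715, size=(4, 2))]
        road = VectorLayer("line", [(LineString(coords), {"class": "rural"})])
        out = merge_cost_surface(lc, roads=road)
        got = {tuple(rc) for rc in
               np.argwhere(out.values == ROAD_CODES["rural"])}
        assert got == _oracle_touched_cells(coords, lc, n_samples=60000)

    def test_feature_order_does_not_matter(self):
        rng = np.random.default_rng(3)
        lc = categorical(np.full((6, 6), 9))
        feats = [(LineString(rng.uniform(0, 540, size=(2, 2))),
                  {"class": cls})
                 for cls in ("rural", "national", "district", "rural")]
        a = merge_cost_surface(lc, roads=VectorLayer("line", feats))
        b = merge_cost_surface(lc, roads=VectorLayer("line", feats[::-1]))
        np.testing.assert_array_equal(a.values, b.values)

    def test_unknown_road_class_rejected(self):
        lc = categorical(np.full((3, 3), 9))
        road = VectorLayer("line", [
            (LineString([(0, 0), (90, 90)]), {"class": "highway"})])
        with pytest.raises(ValueError, match="unknown class"):
            merge_cost_surface(lc, roads=road)


def facility_table(rows):
    return pd.DataFrame(rows, columns=["id", "x", "y", "capacity", "type"])


class TestCleanFacilities:
    def make_surface(self):
        return categorical(np.full((10, 10), 9))

    def test_missingness_tallies_and_percentages(self):
        """113 facilities: 9 missing both, 7 coords only, 3 capacity only
        leaves 94 included (83.2%)."""
        rows = []
        for i in range(113):
            x, y, cap = 405.0, 405.0, 1000.0
            if i < 9:
                x = y = cap = np.nan
            elif i < 16:
                x = y = np.nan
            elif i < 19:
                cap = np.nan
            rows.append((f"F{i}", x, y, cap, "health_centre"))
        fac, rep = clean_facilities(facility_table(rows), self.make_surface())
        assert rep.n_included == len(fac) == 94
        assert (rep.n_missing_both, rep.n_missing_coords_only,
                rep.n_missing_capacity_only) == (9, 7, 3)
        assert rep.pct_included == 83.2
        assert rep.pct_missing_both == 8.0
        assert rep.pct_missing_coords_only == 6.2
        assert rep.pct_missing_capacity_only == 2.7
        assert rep.pct_excluded == 16.8

    def test_empty_strings_count_as_missing(self):
        rows = [("A", "", "", 100.0, "t"), ("B", 45.0, 45.0, "", "t"),
                ("C", 45.0, 135.0, 50.0, "t")]
        fac, rep = clean_facilities(facility_table(rows), self.make_surface())
        assert rep.n_included == 1 and fac[0].id == "C"

    def test_water_sitting_facility_relocated_with_rowcol_tiebreak(self):
        vals = np.full((3, 3), WATER_CODE)
        vals[0, 1] = 9
        vals[1, 0] = 9  # equidistant from center cell (1, 1)
        surface = categorical(vals)
        x, y = surface.cell_center(1, 1)
        fac, rep = clean_facilities(
            facility_table([("A", float(x), float(y), 10.0, "t")]), surface)
        assert rep.n_relocated == 1 and fac[0].relocated
        assert (fac[0].row, fac[0].col) == (0, 1)  # ascending (row, col) wins
        assert (fac[0].x, fac[0].y) == tuple(map(float, surface.cell_center(0, 1)))

    def test_duplicate_id_rejected(self):
        rows = [("A", 45.0, 45.0, 10.0, "t"), ("A", 135.0, 45.0, 10.0, "t")]
        with pytest.raises(ValueError, match="duplicate"):
            clean_facilities(facility_table(rows), self.make_surface())

    def test_non_positive_capacity_rejected(self):
        rows = [("A", 45.0, 45.0, 0.0, "t")]
        with pytest.raises(ValueError, match="capacity"):
            clean_facilities(facility_table(rows), self.make_surface())
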