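"""Tessellation geometry and conservation under gridding."""

import math

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import LineString, Point, box

from routexpose.errors import CoverageError, GeometryError, InvalidConfigError
from routexpose.hexgrid import (
    NoiseClass,
    NoiseScheme,
    aggregate_buildings,
    aggregate_streets,
    assign_noise,
    count_pois,
    get_scheme,
    hexagon_edge_for_area,
    make_grid,
)


class TestNoiseScheme:
    def test_builtin_schemes(self):
        london = get_scheme("london6")
        brisbane = get_scheme("brisbane5")
        assert len(london) == 6 and len(brisbane) == 5
        # ascending loudness, contiguous on the dB axis
        for scheme in (london, brisbane):
            for a, b in zip(scheme.classes, scheme.classes[1:]):
                assert a.high_db == b.low_db
        assert london.classes[1].low_db == 55.0 and london.classes[1].high_db == 60.0
        assert brisbane.classes[-1].low_db == 73.0

    def test_non_contiguous_rejected(self):
        with pytest.raises(InvalidConfigError):
            NoiseScheme("bad", (
                NoiseClass("a", "a", -math.inf, 55.0),
                NoiseClass("b", "b", 56.0, math.inf),
            ))

    def test_unknown_name_rejected(self):
        with pytest.raises(InvalidConfigError):
            get_scheme("paris7")

    def test_json_roundtrip(self):
        london = get_scheme("london6")
        assert NoiseScheme.from_json(london.to_json()) == london


class TestMakeGrid:
    def test_edge_length_closed_form(self):
        grid = make_grid((0, 0, 1000, 1000), cell_area=250_000.0)
        expected = math.sqrt(2 * 250_000.0 / (3 * math.sqrt(3)))
        assert grid.edge_length == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(310.2, abs=0.1)

    def test_cell_areas_match_requested(self):
        grid = make_grid((0, 0, 2000, 2000), cell_area=250_000.0)
        areas = shapely.area(grid.geometries)
        assert np.all(np.abs(areas - 250_000.0) < 1e-6 * 250_000.0)

    def test_congruence(self):
        grid = make_grid((0, 0, 3000, 3000))
        areas = shapely.area(grid.geometries)
        assert (areas.max() - areas.min()) / areas.mean() < 1e-9

    def test_tiny_bbox_still_covered(self):
        grid = make_grid((500, 500, 501, 501), cell_area=250_000.0)
        assert len(grid.cells) >= 1
        covered = sum(g.intersection(box(500, 500, 501, 501)).area for g in grid.geometries)
        assert covered == pytest.approx(1.0, rel=1e-6)

    def test_partition_of_bbox(self):
        """Clipped cell areas sum to the bbox area: the tessellation neither
        gaps nor overlaps."""
        bbox = (0, 0, 2000, 2000)
        grid = make_grid(bbox)
        clip = box(*bbox)
        covered = sum(g.intersection(clip).area for g in grid.geometries)
        assert covered == pytest.approx(4e6, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidConfigError):
            make_grid((0, 0, 100, 100), cell_area=0)
        with pytest.raises(InvalidConfigError):
            make_grid((0, 0, -5, 100))

    def test_stable_cell_ids(self):
        g1 = make_grid((0, 0, 2000, 2000))
        g2 = make_grid((0, 0, 2000, 2000))
        assert (g1.cells[["cell_id", "row", "col"]] == g2.cells[["cell_id", "row", "col"]]).all().all()


def _cell_containing(grid, x, y):
    return grid.cells.iloc[
        grid.tree().query(Point(x, y), predicate="intersects")[0]
    ]


class TestAggregation:
    def test_building_contained_in_one_cell(self):
        grid = make_grid((0, 0, 2000, 2000))
        cell = grid.cells.iloc[10]
        cx, cy = cell["geometry"].centroid.x, cell["geometry"].centroid.y
        out = aggregate_buildings(grid, [box(cx - 5, cy - 5, cx + 5, cy + 5)])
        gained = out.cells["building_area_m2"]
        assert gained.iloc[10] == pytest.approx(100.0, rel=1e-9)
        assert gained.sum() == pytest.approx(100.0, rel=1e-9)

    def test_building_split_across_vertical_edge(self):
        """Adjacent same-row hexagons share a vertical edge; a rectangle
        centred on it splits 50/50."""
        grid = make_grid((0, 0, 3000, 3000))
        row1 = grid.cells[grid.cells["row"] == 2]
        cell = row1.iloc[1]
        hx = cell["geometry"]
        edge_x = hx.bounds[2]  # right vertical edge
        cy = hx.centroid.y
        building = box(edge_x - 10, cy - 5, edge_x + 10, cy + 5)
        out = aggregate_buildings(grid, [building])
        contributions = out.cells.loc[out.cells["building_area_m2"] > 0, "building_area_m2"]
        assert len(contributions) == 2
        assert np.allclose(contributions, 100.0, rtol=1e-9)

    def test_building_area_conserved(self):
        rng = np.random.default_rng(0)
        rects = []
        for _ in range(200):
            x, y = rng.uniform(100, 1900, 2)
            w, h = rng.uniform(5, 60, 2)
            rects.append(box(x, y, x + w, y + h))
        grid = make_grid((0, 0, 2100, 2100))
        out = aggregate_buildings(grid, rects)
        total = sum(r.area for r in rects)
        assert out.cells["building_area_m2"].sum() == pytest.approx(total, rel=1e-6)

    def test_invalid_polygon_named(self):
        grid = make_grid((0, 0, 2000, 2000))
        bowtie = shapely.Polygon([(0, 0), (10, 10), (10, 0), (0, 10)])
        with pytest.raises(GeometryError, match="index 0"):
            aggregate_buildings(grid, [bowtie])

    def test_street_contained_and_split(self):
        grid = make_grid((0, 0, 3000, 3000))
        cell = grid.cells[grid.cells["row"] == 2].iloc[1]["geometry"]
        cx, cy = cell.centroid.x, cell.centroid.y
        out = aggregate_streets(grid, [LineString([(cx - 250, cy), (cx + 250, cy)])])
        inside = out.cells.loc[out.cells["street_length_m"] > 0, "street_length_m"]
        assert len(inside) == 1 and inside.iloc[0] == pytest.approx(500.0, rel=1e-9)

        edge_x = cell.bounds[2]
        seg = LineString([(edge_x - 100, cy), (edge_x + 100, cy)])
        out2 = aggregate_streets(grid, [seg])
        parts = out2.cells.loc[out2.cells["street_length_m"] > 0, "street_length_m"]
        assert len(parts) == 2 and np.allclose(parts, 100.0, rtol=1e-9)

    def test_street_length_conserved(self, city, city_grid):
        total = sum(g.length for g in city.streets["geometry"])
        assert city_grid.cells["street_length_m"].sum() == pytest.approx(total, rel=1e-6)

    def test_poi_counting_and_edge_assignment(self):
        grid = make_grid((0, 0, 3000, 3000))
        cell = grid.cells.iloc[8]["geometry"]
        cx, cy = cell.centroid.x, cell.centroid.y
        pois = pd.DataFrame(
            {
                "geometry": [Point(cx, cy), Point(cx + 1, cy), Point(cx, cy + 1),
                             Point(cell.bounds[2], cy)],  # last sits on a shared edge
                "category": ["retail", "retail", "retail", "medical"],
            }
        )
        out = count_pois(grid, pois)
        assert out.cells["poi_retail"].iloc[8] == 3
        assert out.cells["poi_medical"].sum() == 1  # edge point assigned once

    def test_poi_totals_conserved(self, city, city_grid):
        poi_cols = [f"poi_{c}" for c in city_grid.categories]
        assert city_grid.cells[poi_cols].to_numpy().sum() == len(city.pois)

    def test_unknown_category_rejected(self):
        grid = make_grid((0, 0, 2000, 2000))
        pois = pd.DataFrame({"geometry": [Point(100, 100)], "category": ["casino"]})
        with pytest.raises(InvalidConfigError):
            count_pois(grid, pois)

    def test_idempotent_on_empty_inputs(self, city_grid):
        out = aggregate_buildings(city_grid, [])
        out = aggregate_streets(out, [])
        out = count_pois(out, pd.DataFrame({"geometry": [], "category": []}))
        pd.testing.assert_frame_equal(out.cells, city_grid.cells)


class TestAssignNoise:
    def _one_cell_grid(self):
        grid = make_grid((0, 0, 1200, 1200))
        return grid

    def test_cell_inside_single_class(self, scheme):
        grid = self._one_cell_grid()
        noise = pd.DataFrame({"geometry": [box(-2000, -2000, 4000, 4000)], "noise_class": [2]})
        out = assign_noise(grid, noise, scheme)
        assert (out.cells["noise_class"] == 2).all()

    def test_majority_rule_70_30(self, scheme):
        grid = self._one_cell_grid()
        cell = grid.cells.iloc[5]["geometry"]
        minx, miny, maxx, maxy = cell.bounds
        xsplit = minx + 0.78 * (maxx - minx)  # everything left of this: class 0
        noise = pd.DataFrame(
            {
                "geometry": [box(-2000, -2000, xsplit, 4000), box(xsplit, -2000, 4000, 4000)],
                "noise_class": [0, 1],
            }
        )
        out = assign_noise(grid, noise, scheme)
        assert out.cells["noise_class"].iloc[5] == 0

    def test_exact_tie_breaks_to_louder(self, scheme):
        """Pointy-top hexagons are symmetric about their vertical centreline,
        so a split through the centroid is an exact 50/50 tie."""
        grid = self._one_cell_grid()
        cell = grid.cells.iloc[5]["geometry"]
        xmid = cell.centroid.x
        noise = pd.DataFrame(
            {
                "geometry": [box(-2000, -2000, xmid, 4000), box(xmid, -2000, 4000, 4000)],
                "noise_class": [1, 3],
            }
        )
        out = assign_noise(grid, noise, scheme)
        assert out.cells["noise_class"].iloc[5] == 3
        # and with the louder class on the other side as a control
        noise2 = pd.DataFrame(
            {
                "geometry": [box(-2000, -2000, xmid, 4000), box(xmid, -2000, 4000, 4000)],
                "noise_class": [3, 1],
            }
        )
        out2 = assign_noise(grid, noise2, scheme)
        assert out2.cells["noise_class"].iloc[5] == 3

    def test_coverage_gap_raises(self, scheme):
        grid = self._one_cell_grid()
        noise = pd.DataFrame({"geometry": [box(0, 0, 200, 200)], "noise_class": [0]})
        with pytest.raises(CoverageError):
            assign_noise(grid, noise, scheme)
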