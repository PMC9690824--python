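"""Service layers: radius rules, buffering, overlap, coverage, composite."""

import math

import numpy as np
import pytest
import shapely
from shapely.geometry import box

import greenserve as gs
from greenserve.types import BUFFER, PARK, GreenSpacePolygon

from conftest import raster_count_area


def green(gid, geom, category=PARK):
    return GreenSpacePolygon(id=gid, geometry=geom, category=category)


class TestCoolingRadius:
    def test_zero_crossing(self):
        x0 = math.exp(448.33 / 53.668)
        assert gs.cooling_radius(x0) == pytest.approx(0.0, abs=1e-9)
        assert gs.cooling_radius(x0 * 0.999) == 0.0
        assert gs.cooling_radius(x0 * 1.001) > 0.0

    def test_direct_evaluation_at_e9(self):
        assert gs.cooling_radius(math.exp(9.0)) == pytest.approx(34.682, abs=1e-3)

    def test_small_patches_clamp_to_zero(self):
        assert gs.cooling_radius(1000.0) == 0.0

    def test_monotone_nondecreasing_and_continuous(self):
        areas = np.logspace(2, 6.5, 400)
        radii = np.array([gs.cooling_radius(a) for a in areas])
        assert np.all(np.diff(radii) >= 0)
        # no jump anywhere near the zero crossing
        x0 = math.exp(448.33 / 53.668)
        assert gs.cooling_radius(x0 + 1.0) < 0.02

    def test_rejects_nonpositive_area(self):
        with pytest.raises(gs.ConfigError):
            gs.cooling_radius(0.0)


class TestDisasterRadius:
    @pytest.mark.parametrize(
        "category,area_ha,expected_m",
        [
            (PARK, 0.4, 0.0),
            (PARK, 0.5, 500.0),
            (PARK, 0.9, 500.0),
            (PARK, 5.0, 1000.0),
            (PARK, 25.0, 2000.0),
            (PARK, 50.0, 3000.0),
            (PARK, 120.0, 3000.0),
            (BUFFER, 2.0, 300.0),
            (BUFFER, 0.4, 0.0),
        ],
    )
    def test_size_class_table(self, category, area_ha, expected_m):
        assert gs.disaster_radius(category, area_ha * 1e4) == expected_m

    def test_unknown_category_raises(self):
        with pytest.raises(gs.ConfigError):
            gs.disaster_radius("forest", 1e4)


class TestRecreationRadii:
    def test_scales_are_the_walk_thresholds(self):
        assert gs.recreation_radii() == (420.0, 1250.0)

    def test_walking_distance(self):
        from greenserve.service import walking_distance_m

        assert walking_distance_m(15.0) == pytest.approx(1250.0)
        assert walking_distance_m(5.0) == pytest.approx(416.6667, abs=1e-3)
        assert walking_distance_m(0.0) == 0.0


class TestBuildServiceLayer:
    def area(self, size=10_000.0):
        return gs.StudyArea(boundary=box(0.0, 0.0, size, size))

    def test_disjoint_buffers_have_zero_overlap(self):
        a = green("a", box(1000, 1000, 1100, 1100))
        b = green("b", box(8000, 8000, 8100, 8100))
        layer = gs.build_service_layer([a, b], gs.disaster_rule(), self.area())
        assert layer.overlap.area == 0.0
        assert gs.overlap_stats(layer) == (0.0, 0.0)

    def test_identical_sources_overlap_equals_union(self):
        g1 = green("a", box(4000, 4000, 4200, 4200))
        g2 = green("b", box(4000, 4000, 4200, 4200))
        layer = gs.build_service_layer([g1, g2], gs.disaster_rule(), self.area())
        assert layer.overlap.symmetric_difference(layer.union).area < 1e-6

    def test_overlap_is_subset_of_union_and_union_bounded(self, small_city):
        for rule in (gs.cooling_rule(), gs.recreation_rule(1250.0), gs.disaster_rule()):
            layer = gs.build_service_layer(small_city["greens"], rule, small_city["area"])
            assert layer.overlap.difference(layer.union).area < 1e-6
            assert layer.union.area <= sum(b.area for b in layer.buffers) + 1e-6
            assert layer.union.difference(small_city["area"].boundary).area < 1e-6

    def test_two_parks_lens_matches_raster_oracle(self):
        # two 1 ha parks 1500 m apart under the 1 km disaster radius
        a = green("a", box(3000, 4950, 3100, 5050))
        b = green("b", box(4500, 4950, 4600, 5050))
        layer = gs.build_service_layer([a, b], gs.disaster_rule(), self.area())
        oracle = raster_count_area(layer.overlap, (1500, 3500, 6100, 6500), cell=5.0)
        assert layer.overlap.area == pytest.approx(oracle, rel=0.005)
        oracle_union = raster_count_area(layer.union, (1500, 3500, 6100, 6500), cell=5.0)
        assert layer.union.area == pytest.approx(oracle_union, rel=0.005)

    def test_recreation_excludes_protective_buffers(self):
        park = green("p", box(100, 100, 200, 200), PARK)
        strip = green("s", box(5000, 5000, 5100, 9000), BUFFER)
        layer = gs.build_service_layer([park, strip], gs.recreation_rule(420.0), self.area())
        assert layer.source_ids == ("p",)
        assert not layer.union.intersects(strip.geometry.centroid)

    def test_footprint_served_even_at_zero_radius(self):
        tiny = green("t", box(500, 500, 530, 530))  # 900 m2: cooling radius 0
        layer = gs.build_service_layer([tiny], gs.cooling_rule(), self.area())
        assert layer.union.covers(shapely.Point(515, 515))

    def test_enlarging_radius_never_shrinks_union(self, small_city):
        layer_420 = gs.build_service_layer(
            small_city["greens"], gs.recreation_rule(420.0), small_city["area"]
        )
        layer_1250 = gs.build_service_layer(
            small_city["greens"], gs.recreation_rule(1250.0), small_city["area"]
        )
        assert layer_1250.union.area >= layer_420.union.area
        assert layer_420.union.difference(layer_1250.union).area < 1e-6

    def test_empty_source_list_gives_empty_layer(self):
        layer = gs.build_service_layer([], gs.cooling_rule(), self.area())
        assert layer.union.is_empty and layer.overlap.is_empty


class TestCoverageByZone:
    def _zones(self, n=10, cell=100.0):
        g = gs.GridSpec(xmin=0, ymin=0, cell_size=cell, nrows=n, ncols=n)
        labels = np.zeros(g.shape, dtype=int)
        labels[:, n // 2:] = 1
        return gs.HeatZoneMap(grid=g, labels=labels, breaks=(0.5,), zone_names=("Cold", "Hot"))

    def test_full_coverage_and_empty_layer(self):
        zones = self._zones()
        area = gs.StudyArea(boundary=box(0, 0, 1000, 1000))
        full = gs.ServiceLayer(tag="t", source_ids=(), buffers=(),
                               union=area.boundary, overlap=shapely.Polygon())
        table = gs.coverage_by_zone(full, zones)
        assert all(table["ratio_percent"] == 100.00)
        empty = gs.ServiceLayer(tag="t", source_ids=(), buffers=(),
                                union=shapely.Polygon(), overlap=shapely.Polygon())
        table = gs.coverage_by_zone(empty, zones)
        assert all(table["ratio_percent"] == 0.00)

    def test_half_zone_served(self):
        zones = self._zones()
        served = gs.ServiceLayer(tag="t", source_ids=(), buffers=(),
                                 union=box(0, 0, 250, 1000), overlap=shapely.Polygon())
        table = gs.coverage_by_zone(served, zones)
        cold = table[table.zone == "Cold"].iloc[0]
        assert cold["ratio_percent"] == 50.00
        assert cold["service_area_km2"] == pytest.approx(0.25)

    def test_served_never_exceeds_zone_area(self, small_city):
        g = gs.GridSpec.from_bounds(*small_city["area"].boundary.bounds, 50.0)
        surface = gs.kde_surface(small_city["pois"], 500.0, g)
        zones = gs.classify_heat(surface, method="quantile")
        layer = gs.build_service_layer(small_city["greens"], gs.disaster_rule(),
                                       small_city["area"])
        table = gs.coverage_by_zone(layer, zones)
        assert (table["service_area_km2"] <= table["zone_area_km2"] + 1e-9).all()


class TestComposite:
    def _layer(self, tag, geom):
        return gs.ServiceLayer(tag=tag, source_ids=(), buffers=(),
                               union=geom, overlap=shapely.Polygon())

    def test_idempotent_on_identical_layers(self):
        area = gs.StudyArea(boundary=box(0, 0, 1000, 1000))
        geom = box(100, 100, 700, 700)
        layers = [self._layer(t, geom) for t in ("cooling", "recreation_1250", "disaster")]
        composite = gs.composite_service(layers, area)
        assert composite.symmetric_difference(geom).area < 1e-9

    def test_any_empty_layer_empties_composite(self):
        area = gs.StudyArea(boundary=box(0, 0, 1000, 1000))
        layers = [
            self._layer("cooling", box(0, 0, 500, 500)),
            self._layer("recreation_1250", shapely.Polygon()),
            self._layer("disaster", box(0, 0, 800, 800)),
        ]
        assert gs.composite_service(layers, area).is_empty

    def test_composite_bounded_by_smallest_union(self, small_city):
        layers = [
            gs.build_service_layer(small_city["greens"], r, small_city["area"])
            for r in (gs.cooling_rule(), gs.recreation_rule(1250.0), gs.disaster_rule())
        ]
        composite = gs.composite_service(layers, small_city["area"])
        assert composite.area <= min(l.union.area for l in layers) + 1e-6

    def test_missing_layer_raises(self):
        area = gs.StudyArea(boundary=box(0, 0, 1000, 1000))
        layers = [self._layer("cooling", box(0, 0, 500, 500))]
        with pytest.raises(gs.ConfigError):
            gs.composite_service(layers, area)


class TestOverlapStats:
    def test_printed_style_ratio(self):
        # overlap 2.331 km2 over a 25.237 km2 union -> 9.24%
        union = box(0, 0, 25_237.0, 1000.0)
        overlap = box(0, 0, 2_331.0, 1000.0)
        layer = gs.ServiceLayer(tag="cooling", source_ids=(), buffers=(),
                                union=union, overlap=overlap)
        assert gs.overlap_stats(layer) == (2.331, 9.24)
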