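"""G2SFCA accessibility: decay identities, both catchment steps, conservation."""

import math

import numpy as np
import pytest
from shapely.geometry import box

import greenserve as gs
from greenserve.access import DecayParams, classify_accessibility
from greenserve.types import DemandUnit, GreenSpacePolygon

from conftest import brute_force_2sfca

D0 = 1250.0


def unit(uid, x, y, pop, half=50.0):
    return DemandUnit(id=uid, geometry=box(x - half, y - half, x + half, y + half),
                      population=pop)


def park(pid, x, y, area_m2):
    half = math.sqrt(area_m2) / 2.0
    return GreenSpacePolygon(id=pid, geometry=box(x - half, y - half, x + half, y + half),
                             category="park")


class TestGaussianDecay:
    def test_identity_at_zero_and_threshold(self):
        p = DecayParams(d0=D0)
        assert gs.gaussian_decay(0.0, p) == pytest.approx(1.0, rel=1e-15)
        assert gs.gaussian_decay(D0, p) == pytest.approx(0.0, abs=1e-15)
        assert gs.gaussian_decay(D0 + 1e-9, p) == 0.0
        assert gs.gaussian_decay(10 * D0, p) == 0.0

    def test_half_threshold_value(self):
        # (e^-1/8 - e^-1/2) / (1 - e^-1/2) = 0.7013666 (closed form)
        expected = (math.exp(-0.125) - math.exp(-0.5)) / (1.0 - math.exp(-0.5))
        assert expected == pytest.approx(0.7013665732390044, rel=1e-12)
        assert gs.gaussian_decay(D0 / 2.0, DecayParams(d0=D0)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_strictly_decreasing_on_support(self):
        d = np.linspace(0.0, D0, 500)
        w = gs.gaussian_decay(d, DecayParams(d0=D0))
        assert np.all(np.diff(w) < 0.0)
        assert np.all((w >= 0.0) & (w <= 1.0))

    def test_negative_distance_rejected(self):
        with pytest.raises(gs.ConfigError):
            gs.gaussian_decay(-1.0, DecayParams())


class TestSupplyDemandRatios:
    def test_single_park_single_unit_at_zero_distance(self):
        p = park("p", 0.0, 0.0, 10_000.0)
        u = unit("u", 0.0, 0.0, 100.0)
        table = gs.supply_demand_ratios([p], [u])
        assert table["R"].iloc[0] == pytest.approx(100.0, rel=1e-12)
        assert bool(table["served"].iloc[0])

    def test_out_of_range_park_flagged_unserved(self):
        p = park("p", 0.0, 0.0, 10_000.0)
        u = unit("u", 5000.0, 0.0, 100.0)
        table = gs.supply_demand_ratios([p], [u])
        assert not bool(table["served"].iloc[0])
        assert np.isnan(table["R"].iloc[0])

    def test_two_units_at_half_threshold(self):
        g_half = (math.exp(-0.125) - math.exp(-0.5)) / (1.0 - math.exp(-0.5))
        p = park("p", 0.0, 0.0, 10_000.0)
        us = [unit("a", D0 / 2.0, 0.0, 50.0), unit("b", -D0 / 2.0, 0.0, 50.0)]
        table = gs.supply_demand_ratios([p], us)
        assert table["R"].iloc[0] == pytest.approx(10_000.0 / (g_half * 100.0), rel=1e-12)

    def test_non_park_categories_excluded(self):
        strip = GreenSpacePolygon(id="s", geometry=box(0, 0, 100, 5000), category="buffer")
        u = unit("u", 50.0, 50.0, 10.0)
        table = gs.supply_demand_ratios([strip], [u])
        assert len(table) == 0


class TestAccessibility:
    def test_chained_single_pair(self):
        p = park("p", 0.0, 0.0, 10_000.0)
        u = unit("u", 0.0, 0.0, 100.0)
        result = gs.evaluate_accessibility([p], [u])
        assert result.table["A_m2_per_capita"].iloc[0] == pytest.approx(100.0, rel=1e-12)

    def test_unit_without_reachable_park_scores_zero(self):
        p = park("p", 0.0, 0.0, 10_000.0)
        us = [unit("near", 100.0, 0.0, 10.0), unit("far", 9000.0, 0.0, 10.0)]
        ratios = gs.supply_demand_ratios([p], us)
        A = gs.accessibility_values(us, [p], ratios)
        assert A[1] == 0.0
        assert A[0] > 0.0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            parks = [
                park(f"p{i}", rng.uniform(0, 4000), rng.uniform(0, 4000),
                     rng.uniform(5e3, 5e4))
                for i in range(5)
            ]
            units = [
                unit(f"u{i}", rng.uniform(0, 4000), rng.uniform(0, 4000),
                     rng.uniform(0, 500))
                for i in range(10)
            ]
            ratios = gs.supply_demand_ratios(parks, units)
            A = gs.accessibility_values(units, parks, ratios)
            _, A_oracle = brute_force_2sfca(units, parks, D0)
            assert np.allclose(A, A_oracle, rtol=1e-12, atol=1e-15)

    def test_supply_conservation_many_seeds(self):
        """sum_i D_i A_i == sum of served park areas, the defining 2SFCA law."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            n_p, n_u = rng.integers(1, 8), rng.integers(1, 15)
            parks = [
                park(f"p{i}", rng.uniform(0, 5000), rng.uniform(0, 5000),
                     rng.uniform(5e3, 1e5))
                for i in range(n_p)
            ]
            units = [
                unit(f"u{i}", rng.uniform(0, 5000), rng.uniform(0, 5000),
                     rng.uniform(1.0, 500.0))
                for i in range(n_u)
            ]
            ratios = gs.supply_demand_ratios(parks, units)
            A = gs.accessibility_values(units, parks, ratios)
            pops = np.array([u.population for u in units])
            served_area = ratios.loc[ratios["served"], "area_m2"].sum()
            assert np.dot(pops, A) == pytest.approx(served_area, rel=1e-9)

    def test_supply_scaling_scales_accessibility(self):
        rng = np.random.default_rng(5)
        parks = [park(f"p{i}", rng.uniform(0, 3000), rng.uniform(0, 3000), 2e4)
                 for i in range(4)]
        big = [GreenSpacePolygon(id=g.id, geometry=g.geometry.buffer(0.0), category="park")
               for g in parks]
        units = [unit(f"u{i}", rng.uniform(0, 3000), rng.uniform(0, 3000), 100.0)
                 for i in range(8)]
        ratios = gs.supply_demand_ratios(parks, units)
        A1 = gs.accessibility_values(units, parks, ratios)
        # scale every park area by 3 via a custom ratio table
        ratios3 = ratios.copy()
        ratios3["R"] = ratios3["R"] * 3.0
        A3 = gs.accessibility_values(units, parks, ratios3)
        assert np.allclose(A3, 3.0 * A1, rtol=1e-12)


class TestBenchmark:
    def test_total_area_over_total_population(self):
        parks = [park("a", 0, 0, 60_000.0), park("b", 3000, 0, 40_000.0)]
        units = [unit("u1", 0, 0, 600.0), unit("u2", 100, 0, 400.0)]
        assert gs.per_capita_benchmark(parks, units) == pytest.approx(100.0)

    def test_linear_in_park_area(self, small_city):
        base = gs.per_capita_benchmark(small_city["greens"], small_city["units"])
        doubled = [
            GreenSpacePolygon(
                id=g.id,
                geometry=shapely_scale(g.geometry),
                category=g.category,
            )
            for g in small_city["greens"]
        ]
        assert gs.per_capita_benchmark(doubled, small_city["units"]) == pytest.approx(
            2.0 * base, rel=1e-9
        )

    def test_zero_population_raises(self):
        parks = [park("a", 0, 0, 1e4)]
        with pytest.raises(gs.DataError):
            gs.per_capita_benchmark(parks, [unit("u", 0, 0, 0.0)])


def shapely_scale(geom):
    """Double a polygon's area by stretching one axis."""
    import shapely.affinity

    return shapely.affinity.scale(geom, xfact=2.0, yfact=1.0)


class TestClassification:
    def test_quantile_on_1_to_8_gives_two_per_class(self):
        level4, level3 = classify_accessibility(np.arange(1.0, 9.0))
        assert level4 == ["low"] * 2 + ["medium"] * 2 + ["mid-high"] * 2 + ["high"] * 2
        assert level3 == ["low"] * 2 + ["medium"] * 2 + ["high"] * 4

    def test_degenerate_values_raise(self):
        with pytest.raises(gs.DataError):
            classify_accessibility(np.ones(10))

    def test_labels_monotone_in_value(self):
        rng = np.random.default_rng(77)
        values = rng.gamma(2.0, size=200)
        level4, _ = classify_accessibility(values)
        rank = {"low": 0, "medium": 1, "mid-high": 2, "high": 3}
        order = np.argsort(values)
        codes = np.array([rank[level4[i]] for i in order])
        assert np.all(np.diff(codes) >= 0)
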