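"""Geographic heuristics: nearest-neighbour index, coverage maps, overlap."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from robitt.core import GridSpec, PeriodSpec, TargetPopulation
from robitt.geo import (
    clark_evans_analytic,
    coverage_overlap,
    density_surface,
    nearest_neighbour_index,
    nn_distances,
    nni_by_period,
    periods_sampled_map,
    sample_uniform,
)
from .conftest import make_records

UNIT = box(0, 0, 1, 1)


class TestClarkEvansAnalytic:
    def test_unit_square_corners(self):
        # each corner's nearest neighbour is 1 away: R = 2 * 1 * sqrt(4/1) = 4
        pts = [(0, 0), (0, 1), (1, 0), (1, 1)]
        assert clark_evans_analytic(pts, area=1.0) == pytest.approx(4.0)

    def test_csr_tends_to_one(self, rng):
        pts = rng.uniform(0, 1, (2000, 2))
        assert clark_evans_analytic(pts, 1.0) == pytest.approx(1.0, abs=0.06)


class TestNearestNeighbourIndex:
    def test_csr_index_near_one(self, rng):
        pts = rng.uniform(0, 1, (500, 2))
        res = nearest_neighbour_index(pts, UNIT, n_ref_sims=99, seed=11)
        assert res.defined
        assert res.index == pytest.approx(1.0, abs=0.1)

    def test_coincident_points_give_zero(self):
        res = nearest_neighbour_index([(0.5, 0.5), (0.5, 0.5)], UNIT, n_ref_sims=19, seed=1)
        assert res.index == 0.0

    def test_tight_cluster_below_one(self, rng):
        pts = 0.5 + rng.normal(0, 0.005, (200, 2))  # all within ~1% of the edge length
        res = nearest_neighbour_index(pts, UNIT, n_ref_sims=49, seed=2)
        assert res.index < 0.5

    def test_fewer_than_two_points_undefined(self):
        res = nearest_neighbour_index(np.empty((1, 2)), UNIT, n_ref_sims=9, seed=0)
        assert not res.defined
        assert "fewer than 2" in res.reason

    def test_degenerate_domain_rejected(self, rng):
        line = Polygon([(0, 0), (1, 0), (1, 0), (0, 0)])
        with pytest.raises(ValueError, match="degenerate|area"):
            nearest_neighbour_index(rng.uniform(0, 1, (10, 2)), line, seed=0)

    def test_agrees_with_analytic_oracle_on_rectangle(self, rng):
        """Dual route: simulation-referenced index vs the closed form."""
        pts = rng.uniform(0, 1, (1000, 2)) * [2.0, 1.0]
        sim = nearest_neighbour_index(pts, box(0, 0, 2, 1), n_ref_sims=99, seed=5)
        analytic = clark_evans_analytic(pts, area=2.0)
        assert sim.index == pytest.approx(analytic, abs=0.05)

    def test_scale_invariance(self, rng):
        pts = rng.uniform(0, 1, (300, 2))
        a = nearest_neighbour_index(pts, UNIT, n_ref_sims=49, seed=3)
        b = nearest_neighbour_index(pts * 10, box(0, 0, 10, 10), n_ref_sims=49, seed=3)
        assert b.index == pytest.approx(a.index, abs=1e-9)

    def test_determinism_bit_identical(self, rng):
        pts = rng.uniform(0, 1, (100, 2))
        a = nearest_neighbour_index(pts, UNIT, n_ref_sims=29, seed=17, n_boot=59)
        b = nearest_neighbour_index(pts, UNIT, n_ref_sims=29, seed=17, n_boot=59)
        assert a == b

    def test_haversine_metric(self, rng):
        pts = rng.uniform(0, 1, (100, 2)) + [-78.0, 0.0]
        res = nearest_neighbour_index(pts, box(-78, 0, -77, 1), n_ref_sims=29, seed=4,
                                      metric="haversine")
        assert res.defined and res.index > 0
        # one degree of latitude is ~111 km
        d = nn_distances(np.array([[-78.0, 0.0], [-78.0, 1.0]]), metric="haversine")
        assert d[0] == pytest.approx(111.19, abs=0.5)

    def test_polygon_domain_sampling_stays_inside(self, rng):
        tri = Polygon([(0, 0), (4, 0), (0, 4)])
        pts = sample_uniform(tri, 200, rng)
        import shapely

        assert shapely.intersects_xy(tri, pts[:, 0], pts[:, 1]).all()


class TestNNIByPeriod:
    def _pop(self):
        return TargetPopulation(
            geo_extent=box(0, 0, 1, 1), temporal_extent=(2000, 2019),
            taxa=("t",), spatial_resolution=0.1, temporal_resolution=10,
            grid_origin=(0.0, 0.0),
        )

    def test_thin_period_marked_undefined(self, rng):
        pts = rng.uniform(0, 1, (40, 2))
        df = make_records([("t", x, y, 2003) for x, y in pts] + [("t", 0.5, 0.5, 2015)])
        results = nni_by_period(df, self._pop(), n_ref_sims=19, n_boot=0, seed=1)
        assert [r.defined for r in results] == [True, False]
        assert results[1].reason == "fewer than 2 records"

    def test_identical_point_sets_identical_results(self, rng):
        pts = rng.uniform(0, 1, (50, 2))
        rows = [("t", x, y, 2001) for x, y in pts] + [("t", x, y, 2011) for x, y in pts]
        r1, r2 = nni_by_period(make_records(rows), self._pop(), n_ref_sims=29, n_boot=29, seed=9)
        assert (r1.index, r1.ci_low, r1.ci_high) == (r2.index, r2.ci_low, r2.ci_high)

    def test_bootstrap_interval_ordering_and_coverage(self):
        """Percentile intervals are ordered and cover 1 for CSR data most of the time."""
        hits, total = 0, 15
        for s in range(total):
            pts = np.random.default_rng(1000 + s).uniform(0, 1, (200, 2))
            res = nearest_neighbour_index(pts, UNIT, n_ref_sims=49, seed=s, n_boot=199, level=0.95)
            assert res.ci_low <= res.ci_high
            if res.ci_low <= 1.0 <= res.ci_high:
                hits += 1
        assert hits / total >= 0.6  # nominal 0.95, generous slack for 15 replicates


class TestCoverageMaps:
    GRID = GridSpec(resolution=1.0, origin_lon=0.0, origin_lat=0.0)
    PERIODS = PeriodSpec(2000, 2069, 10)

    def test_periods_sampled_counts(self):
        df = make_records(
            [
                ("t", 0.5, 0.5, 2000),  # cell (0,0), p1
                ("t", 0.6, 0.4, 2025),  # cell (0,0), p3
                ("t", 0.2, 0.8, 2028),  # cell (0,0), p3 again — still 2 periods
                ("t", 3.5, 3.5, 2042),  # cell (3,3), p5 only, many records
                ("t", 3.6, 3.6, 2043),
            ]
        )
        psm = periods_sampled_map(df, self.GRID, self.PERIODS)
        got = {(c, r): n for c, r, n in psm.itertuples(index=False)}
        assert got == {(0, 0): 2, (3, 3): 1}
        assert all(n <= self.PERIODS.n_periods for n in got.values())

    def test_density_surface_counts_and_log10(self):
        df = make_records([("t", 0.5, 0.5, 2001)] * 3 + [("t", 2.5, 2.5, 2015)])
        dens = density_surface(df, self.GRID, self.PERIODS)
        three = dens[(dens["col"] == 0) & (dens["period"] == "p1")]
        assert three["count"].item() == 3
        assert three["log10_count"].item() == pytest.approx(0.4771, abs=1e-4)
        one = dens[(dens["col"] == 2)]
        assert one["log10_count"].item() == 0.0
        assert dens["count"].sum() == len(df)  # conservation, zero cells absent

    def test_coverage_overlap(self):
        # p1 samples cells {(0,0),(1,1)}; p2 samples {(1,1),(2,2)} -> 1/3
        df = make_records(
            [
                ("t", 0.5, 0.5, 2001), ("t", 1.5, 1.5, 2003),
                ("t", 1.5, 1.5, 2012), ("t", 2.5, 2.5, 2017),
            ]
        )
        assert coverage_overlap(df, self.GRID, self.PERIODS, "p1", "p2") == pytest.approx(1 / 3)
        assert coverage_overlap(df, self.GRID, self.PERIODS, "p1", "p1") == 1.0
        assert coverage_overlap(df, self.GRID, self.PERIODS, "p3", "p4") is None
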