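"""Grid assignment, temporal binning and population filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import box

from robitt.core import (
    GridSpec,
    OccurrenceRecord,
    PeriodSpec,
    TargetPopulation,
    assign_cell,
    assign_period,
    count_periods,
    filter_to_population,
    jaccard,
)
from .conftest import make_records


class TestGrid:
    @pytest.mark.parametrize(
        "lon,lat,res,expected",
        [
            (-78.5, -1.5, 1.0, (101, 88)),  # floor((lon+180)/res), floor((lat+90)/res)
            (-179.0, -89.0, 1.0, (1, 1)),  # point exactly on a lower cell edge
            (179.999, 89.999, 1.0, (359, 179)),
        ],
    )
    def test_cell_assignment(self, lon, lat, res, expected):
        grid = GridSpec(resolution=res)
        rec = OccurrenceRecord("t", lon, lat, 2000)
        assert assign_cell(rec, grid) == expected

    def test_halving_resolution_splits_cells(self):
        # 0.3 and 0.7 degrees apart straddle a 0.5-degree edge but share a 1-degree cell
        coarse, fine = GridSpec(1.0), GridSpec(0.5)
        a, b = (0.3, 0.3), (0.7, 0.3)
        assert coarse.cell(*a) == coarse.cell(*b)
        assert fine.cell(*a) != fine.cell(*b)

    def test_non_finite_coordinate_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            GridSpec(1.0).cells(np.array([0.0, np.nan]), np.array([0.0, 0.0]))

    @given(
        lon=st.floats(-180, 180, allow_nan=False),
        lat=st.floats(-90, 90, allow_nan=False),
        res=st.sampled_from([0.25, 0.5, 1.0, 2.0]),
    )
    @settings(max_examples=100, deadline=None)
    def test_cell_assignment_is_total_and_idempotent(self, lon, lat, res):
        grid = GridSpec(res)
        col, row = grid.cell(lon, lat)
        # the point lies inside the half-open cell it was assigned to,
        # up to one floating-point rounding of the division
        edge = grid.origin_lon + col * res
        assert edge - res * 1e-9 <= lon < edge + res
        assert grid.cell(lon, lat) == (col, row)


class TestPeriods:
    @pytest.mark.parametrize(
        "year,expected", [(1950, "p1"), (1959, "p1"), (1960, "p2"), (1969, "p2"), (2019, "p7")]
    )
    def test_decadal_labels(self, year, expected, decadal_periods):
        assert assign_period(year, decadal_periods) == expected

    @pytest.mark.parametrize(
        "start,end,width,n",
        [(1950, 2019, 10, 7), (2000, 2000, 10, 1), (1950, 2020, 10, 8)],
    )
    def test_count_periods(self, start, end, width, n):
        assert count_periods(PeriodSpec(start, end, width)) == n

    def test_truncated_final_period(self):
        p = PeriodSpec(1950, 2020, 10)
        assert p.bounds(8) == (2020, 2020)
        assert p.bounds(7) == (2010, 2019)

    def test_out_of_extent_year_rejected(self, decadal_periods):
        with pytest.raises(ValueError):
            decadal_periods.index(1949)

    @given(
        start=st.integers(1900, 2000),
        span=st.integers(0, 150),
        width=st.integers(1, 25),
    )
    @settings(max_examples=100, deadline=None)
    def test_partition_property(self, start, span, width):
        """Bins cover the extent exactly once and bound the span tightly."""
        p = PeriodSpec(start, start + span, width)
        n = p.n_periods
        assert n * width >= span + 1 > (n - 1) * width
        # every year maps to exactly one period whose bounds contain it
        for year in range(start, start + span + 1, max(1, span // 7 or 1)):
            idx = p.index(year)
            lo, hi = p.bounds(idx)
            assert lo <= year <= hi


class TestFilterToPopulation:
    def test_exclusion_tally_and_precedence(self, unit_pop):
        records = make_records(
            [
                ("Amazilia amabilis", 5, 5, 2005),
                ("Colibri coruscans", 5, 5, 2010),
                ("Amazilia amabilis", 5, 5, 2019),
                ("Amazilia amabilis", 50, 5, 2005),   # outside extent
                ("Amazilia amabilis", 5, 5, 1949),    # outside time
            ]
        )
        kept, tally = filter_to_population(records, unit_pop)
        assert len(kept) == 3
        assert tally == {"geo": 1, "time": 1, "taxon": 0}

    def test_record_failing_geo_and_time_counted_under_geo(self, unit_pop):
        records = make_records([("Amazilia amabilis", 50, 5, 1900)])
        _, tally = filter_to_population(records, unit_pop)
        assert tally == {"geo": 1, "time": 0, "taxon": 0}

    def test_identity_when_all_inside(self, unit_pop):
        records = make_records([("Amazilia amabilis", 1, 1, 2000), ("Colibri coruscans", 9, 9, 2019)])
        kept, tally = filter_to_population(records, unit_pop)
        assert len(kept) == len(records)
        assert sum(tally.values()) == 0

    @given(
        data=st.lists(
            st.tuples(
                st.sampled_from(["Amazilia amabilis", "Colibri coruscans", "Passer domesticus"]),
                st.floats(-20, 30, allow_nan=False),
                st.floats(-20, 30, allow_nan=False),
                st.integers(1990, 2030),
            ),
            max_size=60,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_conservation(self, data):
        pop = TargetPopulation(
            geo_extent=box(0, 0, 10, 10), temporal_extent=(2000, 2019),
            taxa=("Amazilia amabilis", "Colibri coruscans"),
            spatial_resolution=1.0, temporal_resolution=10, grid_origin=(0.0, 0.0),
        )
        records = make_records(data)
        kept, tally = filter_to_population(records, pop)
        assert len(records) == len(kept) + sum(tally.values())


class TestJaccard:
    @given(
        a=st.sets(st.integers(0, 20), max_size=15),
        b=st.sets(st.integers(0, 20), max_size=15),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_set_arithmetic_oracle(self, a, b):
        got = jaccard(a, b)
        if not a and not b:
            assert got is None
        else:
            assert got == pytest.approx(len(a & b) / len(a | b))
            assert 0.0 <= got <= 1.0

    def test_examples(self):
        assert jaccard({"A", "B"}, {"B", "C"}) == pytest.approx(1 / 3)
        assert jaccard({"A"}, {"A"}) == 1.0
        assert jaccard({"A"}, {"B"}) == 0.0


class TestTargetPopulation:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="taxa"):
            TargetPopulation(box(0, 0, 1, 1), (2000, 2010), (), 1.0, 10)
        with pytest.raises(ValueError, match="temporal_extent"):
            TargetPopulation(box(0, 0, 1, 1), (2010, 2000), ("t",), 1.0, 10)
        with pytest.raises(ValueError, match="positive area"):
            TargetPopulation(box(0, 0, 0, 0), (2000, 2010), ("t",), 1.0, 10)

    def test_bbox_and_geojson_extents(self):
        pop = TargetPopulation((0, 0, 10, 10), (2000, 2010), ("t",), 1.0, 10)
        assert pop.geo_extent.area == 100
        gj = {"type": "Polygon", "coordinates": [[[0, 0], [4, 0], [4, 4], [0, 4], [0, 0]]]}
        pop2 = TargetPopulation(gj, (2000, 2010), ("t",), 1.0, 10)
        assert pop2.geo_extent.area == 16

    def test_config_round_trip(self, unit_pop, tmp_path):
        import yaml

        cfg = {
            "geo_extent": [0, 0, 10, 10],
            "temporal_extent": [2000, 2019],
            "taxa": list(unit_pop.taxa),
            "spatial_resolution": 1.0,
            "temporal_resolution": 10,
            "grid_origin": [0.0, 0.0],
        }
        path = tmp_path / "pop.yaml"
        path.write_text(yaml.safe_dump(cfg))
        loaded = TargetPopulation.from_config(path)
        assert loaded.to_dict() == unit_pop.to_dict()
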