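"""Distances, per-interval ranks, daily medians, cumulative curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import herdrank as hr
from herdrank.ranking import METRES_PER_DEG_LAT

from conftest import make_median_table

DEG_PER_M_LAT = 1.0 / METRES_PER_DEG_LAT


class TestHaversine:
    def test_identical_points(self):
        assert hr.haversine_m(55.0, 8.0, 55.0, 8.0) == 0.0

    def test_one_degree_meridian_arc(self):
        # closed form: R * pi/180 for one degree along a meridian
        assert hr.haversine_m(55.0, 8.0, 56.0, 8.0) == pytest.approx(111195, abs=1)

    @given(
        lat1=st.floats(-89, 89), lon1=st.floats(-179, 179),
        lat2=st.floats(-89, 89), lon2=st.floats(-179, 179),
    )
    @settings(deadline=None, max_examples=50)
    def test_symmetry(self, lat1, lon1, lat2, lon2):
        d1 = hr.haversine_m(lat1, lon1, lat2, lon2)
        d2 = hr.haversine_m(lat2, lon2, lat1, lon1)
        assert d1 == pytest.approx(d2, rel=1e-12, abs=1e-9)

    def test_invalid_coordinates(self):
        with pytest.raises(ValueError):
            hr.haversine_m(95.0, 8.0, 55.0, 8.0)
        with pytest.raises(ValueError):
            hr.haversine_m(55.0, 200.0, 55.0, 8.0)


class TestDistanceMatrix:
    def test_collinear_meridian_points(self):
        lats = [55.0, 55.0 + 100 * DEG_PER_M_LAT, 55.0 + 300 * DEG_PER_M_LAT]
        d = hr.interval_distance_matrix(lats, [8.0, 8.0, 8.0])
        assert d[0, 1] == pytest.approx(100, abs=0.01)
        assert d[0, 2] == pytest.approx(300, abs=0.01)
        assert d[1, 2] == pytest.approx(200, abs=0.01)

    def test_coincident_herd_gives_zero_matrix(self):
        d = hr.interval_distance_matrix([55.42] * 17, [8.40] * 17)
        assert np.all(d == 0.0)

    def test_symmetry_and_zero_diagonal(self, rng):
        lats = 55.4 + rng.normal(0, 0.001, 12)
        lons = 8.4 + rng.normal(0, 0.001, 12)
        d = hr.interval_distance_matrix(lats, lons)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0.0)
        assert np.all(d >= 0.0)


class TestMedianNeighbourDistance:
    def test_equidistant_cow(self):
        d = np.full((4, 4), 50.0)
        np.fill_diagonal(d, 0.0)
        assert hr.median_neighbour_distance(d, 0) == 50.0

    def test_even_count_median(self):
        # cow 0's off-diagonal row is {1, 2, 3, 4} -> 2.5
        d = np.zeros((5, 5))
        d[0, 1:] = d[1:, 0] = [1.0, 2.0, 3.0, 4.0]
        assert hr.median_neighbour_distance(d, 0) == 2.5

    def test_matches_sort_oracle(self, rng):
        a = rng.uniform(1, 500, (17, 17))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0.0)
        meds = hr.median_neighbour_distances(d)
        for i in range(17):
            row = np.sort(np.delete(d[i], i))
            oracle = (row[7] + row[8]) / 2.0  # middle pair of 16
            assert meds[i] == pytest.approx(oracle)


class TestRankWithinInterval:
    def test_strictly_increasing(self):
        ranks = hr.rank_within_interval(np.arange(17) + 10.0)
        assert list(ranks) == list(range(1, 18))

    def test_tied_smallest_get_midrank(self):
        ranks = hr.rank_within_interval([5.0, 5.0, 7.0])
        assert list(ranks) == [1.5, 1.5, 3.0]

    @given(st.lists(st.integers(0, 5), min_size=2, max_size=17))
    @settings(deadline=None, max_examples=200)
    def test_rank_sum_conservation(self, values):
        n = len(values)
        ranks = hr.rank_within_interval(np.asarray(values, dtype=float))
        assert ranks.sum() == pytest.approx(n * (n + 1) / 2)
        assert ranks.min() >= 1.0


class TestDailyMedianRank:
    def _frame(self, ranks, cow="Cow01", day="2023-08-15"):
        return pd.DataFrame({
            "day": pd.to_datetime(day).date(), "interval_index": range(len(ranks)),
            "cow_id": cow, "median_distance_m": 1.0, "n_present": 17,
            "rank": ranks,
        })

    def test_constant_rank(self):
        out = hr.daily_median_rank(self._frame([5.0] * 96))
        assert out.iloc[0]["median_rank"] == 5.0
        assert out.iloc[0]["n_intervals_used"] == 96

    def test_even_count(self):
        out = hr.daily_median_rank(self._frame([3.0, 7.0]))
        assert out.iloc[0]["median_rank"] == 5.0

    def test_matches_numpy_median_oracle(self, rng):
        ranks = rng.integers(1, 18, 50).astype(float)
        out = hr.daily_median_rank(self._frame(list(ranks)))
        assert out.iloc[0]["median_rank"] == np.median(ranks)


class TestCumulativeCurve:
    def _daily(self, per_cow):
        rows = []
        for cow, ranks in per_cow.items():
            for d, r in enumerate(ranks):
                rows.append({"cow_id": cow,
                             "day": pd.Timestamp("2023-08-15").date()
                             + pd.Timedelta(days=d),
                             "median_rank": r, "n_intervals_used": 96})
        return pd.DataFrame(rows)

    def test_constant_rank_total(self):
        curves = hr.cumulative_curve(self._daily({"Cow01": [9.0] * 45}))
        assert hr.final_cumulative(curves)["Cow01"] == 405.0

    def test_single_day(self):
        curves = hr.cumulative_curve(self._daily({"Cow01": [7.0]}))
        assert list(curves["cumulative"]) == [7.0]

    def test_final_equals_sum_and_monotone(self, rng):
        ranks = list(rng.uniform(1, 17, 30))
        curves = hr.cumulative_curve(self._daily({"Cow01": ranks}))
        assert hr.final_cumulative(curves)["Cow01"] == pytest.approx(sum(ranks))
        assert (np.diff(curves["cumulative"]) >= 0).all()

    def test_carry_forward_adds_nothing_on_gap_days(self):
        daily = self._daily({"Cow01": [4.0, 4.0], "Cow02": [5.0, 5.0]})
        daily = daily.drop(daily[(daily.cow_id == "Cow01")].index[-1])
        curves = hr.cumulative_curve(daily, policy="carry-forward")
        assert hr.final_cumulative(curves)["Cow01"] == 4.0

    def test_impute_uses_herd_median(self):
        daily = self._daily({"Cow01": [4.0, 4.0], "Cow02": [5.0, 5.0],
                             "Cow03": [9.0, 9.0]})
        daily = daily.drop(daily[(daily.cow_id == "Cow01")].index[-1])
        curves = hr.cumulative_curve(daily, policy="impute-herd-median")
        # day-2 herd median over Cow02, Cow03 is 7
        assert hr.final_cumulative(curves)["Cow01"] == 11.0


class TestTableStages:
    def test_label_invariance(self, rng):
        med = make_median_table(5, 2, 4, rng)
        swap = {"Cow01": "Cow05", "Cow05": "Cow01"}
        relabelled = med.assign(cow_id=med["cow_id"].replace(swap))
        a = hr.rank_distances(med)
        b = hr.rank_distances(relabelled)
        merged = a.merge(
            b.assign(cow_id=b["cow_id"].replace(swap)),
            on=["day", "interval_index", "cow_id"], suffixes=("_a", "_b"),
        )
        assert len(merged) == len(a)
        assert (merged["rank_a"] == merged["rank_b"]).all()

    def test_scale_invariance_of_ranks(self, rng):
        med = make_median_table(8, 3, 6, rng)
        scaled = med.assign(median_distance_m=med["median_distance_m"] * 3.7)
        assert (hr.rank_distances(med)["rank"]
                == hr.rank_distances(scaled)["rank"]).all()

    def test_complete_only_drops_gappy_intervals(self, rng):
        med = make_median_table(5, 1, 4, rng)
        med = med.drop(index=0)  # one cow missing from interval 0
        out = hr.rank_distances(med, policy="complete-only", herd_size=5)
        assert 0 not in set(out["interval_index"])
        present = hr.rank_distances(med, policy="present-only")
        assert 0 in set(present["interval_index"])

    def test_distances_from_positions_match_direct_matrix(self, rng):
        lat0, lon0 = 55.42, 8.40
        lats = lat0 + rng.normal(0, 50, 6) / METRES_PER_DEG_LAT
        lons = lon0 + rng.normal(0, 50, 6) / (
            METRES_PER_DEG_LAT * np.cos(np.radians(lat0)))
        iv = pd.DataFrame({
            "cow_id": [f"C{i}" for i in range(6)],
            "day": pd.Timestamp("2023-08-15").date(),
            "interval_index": 0, "lat_med": lats, "lon_med": lons,
            "n_messages": 1,
        })
        med = hr.interval_median_distances(iv)
        d = hr.interval_distance_matrix(lats, lons)
        np.testing.assert_allclose(
            med["median_distance_m"], hr.median_neighbour_distances(d)
        )

    def test_single_cow_interval_skipped(self):
        iv = pd.DataFrame({
            "cow_id": ["C0"], "day": pd.Timestamp("2023-08-15").date(),
            "interval_index": [0], "lat_med": [55.4], "lon_med": [8.4],
            "n_messages": [1],
        })
        assert len(hr.interval_median_distances(iv)) == 0
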