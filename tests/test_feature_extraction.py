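"""Spatial primitives, DBSCAN locations, home detection, and the feature
registries (33 daily, 38 period, 170 GPS, 6 step)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import canonical_renumber, dbscan_oracle, random_blob_trajectory
from mobisense import feature_extraction as fx

M = 1.0 / 111_320.0  # ~degrees latitude per meter


def _points_at(offsets_m, lat0=40.0, lon0=-100.0):
    """Points displaced north by the given meters from a base location."""
    lat = np.array([lat0 + o * M for o in offsets_m])
    lon = np.full(len(offsets_m), lon0)
    return lat, lon


class TestHaversine:
    def test_identity_is_zero(self):
        assert fx.haversine_m(12.3, 45.6, 12.3, 45.6) == 0.0

    def test_one_degree_meridian_arc(self):
        # closed form: pi/180 * 6_371_000
        expected = np.pi / 180.0 * 6_371_000.0
        assert fx.haversine_m(0.0, 0.0, 1.0, 0.0) == pytest.approx(expected, abs=0.01)
        assert expected == pytest.approx(111194.93, abs=0.01)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(st.floats(-80, 80), st.floats(-170, 170),
                     st.floats(-80, 80), st.floats(-170, 170)))
    def test_symmetry_and_nonnegativity(self, pts):
        a, b, c, d = pts
        x = fx.haversine_m(a, b, c, d)
        assert x == pytest.approx(fx.haversine_m(c, d, a, b), rel=1e-12)
        assert x >= 0

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            fx.haversine_m(np.nan, 0.0, 1.0, 0.0)


class TestClusterLocations:
    def test_identical_points_one_cluster(self):
        lat, lon = _points_at([0] * 5)
        a = fx.cluster_locations(lat, lon)
        assert a.n_clusters == 1
        assert (a.labels == 0).all()

    def test_below_min_pts_all_noise(self):
        lat, lon = _points_at([0, 5])
        a = fx.cluster_locations(lat, lon)
        assert a.n_clusters == 0
        assert (a.labels == fx.NOISE).all()

    def test_tight_triplet_plus_far_noise_point(self):
        lat, lon = _points_at([0, 10, 20, 1000])
        a = fx.cluster_locations(lat, lon)
        oracle = dbscan_oracle(lat, lon, 30.0, 3)
        assert list(a.labels) == [0, 0, 0, fx.NOISE]
        assert list(canonical_renumber(oracle)) == list(a.labels)

    def test_matches_bruteforce_oracle_on_random_trajectories(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            lat, lon = random_blob_trajectory(rng, max_points=120)
            ours = fx.cluster_locations(lat, lon).labels
            oracle = canonical_renumber(dbscan_oracle(lat, lon, 30.0, 3))
            assert list(ours) == list(oracle)

    def test_centroid_inside_member_bounding_box(self):
        rng = np.random.default_rng(5)
        lat, lon = random_blob_trajectory(rng)
        a = fx.cluster_locations(lat, lon)
        for cid, (cy, cx) in a.centroids.items():
            m = a.labels == cid
            assert lat[m].min() <= cy <= lat[m].max()
            assert lon[m].min() <= cx <= lon[m].max()


class TestDetectHome:
    def _assignment(self, labels):
        ids = sorted(set(labels) - {-1})
        return fx.ClusterAssignment(labels=np.array(labels),
                                    centroids={i: (0.0, 0.0) for i in ids})

    def test_single_cluster_is_home(self):
        a = self._assignment([0, 0, 0])
        assert fx.detect_home(a, np.array([12.0, 13.0, 14.0])) == 0

    def test_night_records_beat_total_count(self):
        labels = [0] * 10 + [1] * 50
        hours = np.array([23.0] * 10 + [12.0] * 50)
        assert fx.detect_home(self._assignment(labels), hours) == 0

    def test_no_night_records_falls_back_to_biggest_cluster(self):
        labels = [0] * 3 + [1] * 7
        hours = np.full(10, 12.0)
        assert fx.detect_home(self._assignment(labels), hours) == 1

    def test_no_clusters_returns_none(self):
        a = self._assignment([-1, -1])
        assert fx.detect_home(a, np.array([1.0, 2.0])) is None


class TestEntropyAndRoutine:
    def test_single_place_zero_entropy(self):
        assert fx.shannon_entropy([1.0]) == 0.0
        assert fx.shannon_entropy([1.0], normalized=True) == 0.0

    def test_uniform_maximum(self):
        assert fx.shannon_entropy([0.25] * 4) == pytest.approx(np.log(4), abs=1e-12)
        assert fx.shannon_entropy([0.25] * 4, normalized=True) == pytest.approx(1.0)

    def test_hand_evaluated_mixture(self):
        # -(0.5 ln 0.5 + 2 * 0.25 ln 0.25) = 1.0397...
        assert fx.shannon_entropy([0.5, 0.25, 0.25]) == pytest.approx(1.039720, abs=1e-5)

    def test_negative_input_raises(self):
        with pytest.raises(ValueError):
            fx.shannon_entropy([-0.1, 1.1])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8))
    def test_entropy_bounds(self, weights):
        p = np.array(weights) / np.sum(weights)
        h = fx.shannon_entropy(p)
        assert -1e-12 <= h <= np.log(len(p)) + 1e-12
        assert 0.0 <= fx.shannon_entropy(p, normalized=True) <= 1.0 + 1e-12

    def test_routine_index_identical_days(self):
        assert fx.routine_index([{0: 0.6, 1: 0.4}] * 5) == pytest.approx(1.0)

    def test_routine_index_disjoint_days(self):
        assert fx.routine_index([{0: 1.0}, {1: 1.0}, {2: 1.0}]) == 0.0

    def test_routine_index_hand_case(self):
        assert fx.routine_index([{0: 1.0}, {0: 0.5, 1: 0.5}]) == pytest.approx(0.5)


class TestCircadianMovement:
    def test_stationary_trajectory_hits_floor(self):
        t = np.linspace(0, 14 * 24, 500)
        lat = np.full(500, 40.0)
        lon = np.full(500, -100.0)
        assert fx.circadian_movement(t, lat, lon) == pytest.approx(np.log(1e-10))

    def test_24h_sinusoid_concentrates_in_band(self):
        """The 23.5-24.5 h band dominates a 3-40 h band sweep.

        Over a 14-day window the spectral peak at 24 h has a Rayleigh width
        of ~1.7 h, so adjacent bands unavoidably share peak energy; the
        concentration check therefore asserts dominance over every resolved
        (non-adjacent) band rather than a fixed fraction of the total.
        """
        t = np.linspace(0, 14 * 24, 2000)
        y = 0.01 * np.sin(2 * np.pi * t / 24.0)
        band = fx._ls_band_energy(t, y, 23.5, 24.5)
        sweep = {p: fx._ls_band_energy(t, y, p, p + 1.0)
                 for p in np.arange(3.0, 40.0, 1.0)}
        assert band >= max(sweep.values())
        resolved = [v for p, v in sweep.items() if abs(p + 0.5 - 24.0) > 2.0]
        assert band > 10 * max(resolved)

    def test_12h_sinusoid_has_little_24h_energy(self):
        t = np.linspace(0, 14 * 24, 2000)
        y24 = 0.01 * np.sin(2 * np.pi * t / 24.0)
        y12 = 0.01 * np.sin(2 * np.pi * t / 12.0)
        e24 = fx._ls_band_energy(t, y24, 23.5, 24.5)
        e12 = fx._ls_band_energy(t, y12, 23.5, 24.5)
        assert e12 < 0.10 * e24


def _simple_day(labels_seq, minutes, lat=None, lon=None, home_id=0):
    """Build a daily-feature call from a label sequence."""
    t = np.array(minutes, dtype=float) * 60.0
    n = len(labels_seq)
    if lat is None:
        lat, lon = _points_at([0 if l == 0 else 500 for l in labels_seq])
    return fx.compute_daily_features(t, lat, lon, np.array(labels_seq),
                                     home=(40.0, -100.0), home_id=home_id)


class TestDailyFeatures:
    def test_all_home_day(self):
        row = _simple_day([0, 0, 0, 0], [0, 10, 20, 30])
        assert row["proportion_time_home"] == 1.0
        assert row["num_location_changes"] == 0
        assert row["entropy"] == 0.0

    def test_alternating_home_work_counts_three_changes(self):
        row = _simple_day([0, 1, 0, 1], [0, 60, 120, 180])
        assert row["num_location_changes"] == 3

    def test_noise_records_are_transparent(self):
        row = _simple_day([0, -1, 0, 1], [0, 60, 120, 180])
        assert row["num_location_changes"] == 1

    def test_two_identical_points_zero_distance(self):
        lat, lon = _points_at([0, 0])
        row = fx.compute_daily_features(np.array([0.0, 60.0]), lat, lon,
                                        np.array([0, 0]), (40.0, -100.0), 0)
        assert row["total_distance_m"] == 0.0

    def test_registry_size(self):
        row = _simple_day([0, 1], [0, 60])
        assert set(row) == set(fx.DAILY_FEATURES)
        assert len(row) == 33


class TestPeriodAndAggregate:
    def test_two_point_radius_of_gyration_is_half_distance(self):
        lat, lon = _points_at([0, 1000])
        d = fx.haversine_m(lat[0], lon[0], lat[1], lon[1])
        t = np.array([0.0, 3600.0])
        row, _ = fx.extract_participant_features(t, lat, lon)
        assert row["radius_of_gyration_14d_m"] == pytest.approx(d / 2, rel=1e-3)

    def test_single_cluster_participant(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 3 * 86400.0, 200))
        lat = 40.0 + rng.normal(0, 3 * M, 200)
        lon = np.full(200, -100.0) + rng.normal(0, 3 * M, 200)
        row, assignment = fx.extract_participant_features(t, lat, lon)
        assert row["num_significant_locations"] == 1
        assert row["entropy_14d"] == 0.0
        assert row["max_distance_from_home_14d_m"] < 5 * 30.0

    def test_aggregate_hand_values_and_counts(self):
        rows = pd.DataFrame([{f: np.nan for f in fx.DAILY_FEATURES}
                             for _ in range(3)])
        rows["num_records"] = [1.0, 2.0, 3.0]
        agg = fx.aggregate_daily_rows(rows)
        assert len(agg) == 132
        assert agg["num_records__mean"] == 2.0
        assert agg["num_records__min"] == 1.0
        assert agg["num_records__max"] == 3.0
        assert agg["num_records__sd"] == pytest.approx(1.0)  # sample SD

    def test_single_day_sd_is_missing(self):
        rows = pd.DataFrame([{f: 1.0 for f in fx.DAILY_FEATURES}])
        agg = fx.aggregate_daily_rows(rows)
        assert np.isnan(agg["num_records__sd"])
        assert agg["num_records__mean"] == 1.0


class TestStepFeatures:
    def test_constant_fortnight_from_monday(self):
        dates = pd.date_range("2021-03-01", periods=14)  # Monday start
        out = fx.compute_step_features(dates, [5000] * 14)
        assert out["steps__mean"] == 5000
        assert out["steps__sd"] == 0.0
        assert out["steps__sum"] == 70000
        assert out["steps__weekday_weekend_diff"] == 0.0

    def test_single_day_degenerate(self):
        out = fx.compute_step_features(pd.date_range("2021-03-01", periods=1), [100])
        assert np.isnan(out["steps__sd"])
        assert np.isnan(out["steps__weekday_weekend_diff"])

    def test_exactly_six_values(self):
        out = fx.compute_step_features(pd.date_range("2021-03-01", periods=5),
                                       [1, 2, 3, 4, 5])
        assert len(out) == 6


class TestAssembleAndExtract:
    def test_block_size_mismatch_raises(self):
        with pytest.raises(ValueError, match="38"):
            fx.assemble_features({}, {"x": 1.0}, {}, {})

    def test_count_contract_and_stable_columns(self, small_dataset):
        gps_cols = fx.gps_feature_columns()
        assert len(gps_cols) == 170
        feats = small_dataset.features
        assert list(feats.columns[:170]) == gps_cols
        assert list(feats.columns[170:176]) == list(fx.STEP_FEATURES)
        assert all(c.startswith("demo_") for c in feats.columns[176:])

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 5 * 86400.0, 400))
        base = rng.choice([0, 600, 1200], size=400)
        lat, lon = _points_at(base + rng.normal(0, 5, 400))
        row1, _ = fx.extract_participant_features(t, lat, lon)
        row2, _ = fx.extract_participant_features(t, lat + 0.002, lon + 0.002)
        skip = {"location_variance_14d"}
        for k, v in row1.items():
            if k in skip or not np.isfinite(v):
                continue
            assert row2[k] == pytest.approx(v, rel=0.02, abs=1.5), k
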