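import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mixedstock as ms
from mixedstock.tracks import (
    EARTH_RADIUS_KM,
    LandMask,
    Track,
    TrackPoint,
    apply_filter_pipeline,
    filter_class,
    filter_land,
    filter_speed,
    haversine_km,
    read_tracks,
    summarize_cohort,
    summarize_track,
    write_tracks,
)


def make_track(points_spec, track_id="T1", t0="2015-06-01T00:00:00Z"):
    """points_spec: list of (minutes, lon, lat[, loc_class])."""
    start = pd.Timestamp(t0)
    pts = []
    for spec in points_spec:
        minutes, lon, lat = spec[:3]
        lc = spec[3] if len(spec) > 3 else "G"
        pts.append(
            TrackPoint(track_id, start + pd.Timedelta(minutes=minutes), lon, lat, lc)
        )
    return Track(track_id, pts)


class TestHaversine:
    def test_identical_points(self):
        assert haversine_km((-61.0, 14.5), (-61.0, 14.5)) == 0.0

    def test_one_degree_along_equator(self):
        expected = 2 * math.pi * EARTH_RADIUS_KM / 360
        assert haversine_km((0.0, 0.0), (1.0, 0.0)) == pytest.approx(expected)

    def test_antipodal_points_half_circumference(self):
        assert haversine_km((0.0, 0.0), (-180.0, 0.0)) == pytest.approx(
            math.pi * EARTH_RADIUS_KM
        )

    def test_symmetry(self):
        a, b = (-61.2, 14.1), (-55.9, 5.3)
        assert haversine_km(a, b) == haversine_km(b, a)


class TestLandMask:
    def test_ascii_grid_round_trip(self, coastal_mask, tmp_path):
        path = tmp_path / "mask.asc"
        coastal_mask.to_ascii_grid(path)
        back = LandMask.from_ascii_grid(path)
        assert np.array_equal(back.grid, coastal_mask.grid)
        assert back.cell_size == coastal_mask.cell_size
        assert back.xll == coastal_mask.xll and back.yll == coastal_mask.yll

    def test_land_and_sea_lookup(self, coastal_mask):
        assert not coastal_mask.is_land(-61.0, 14.5)  # open ocean
        assert coastal_mask.is_land(-47.0, 14.5)  # the land strip

    def test_boundary_point_goes_to_lower_cell(self):
        # two columns: land | sea; boundary at lon=1.0 must resolve to the
        # land cell (lower index)
        mask = LandMask(grid=np.array([[1, 0]]), xll=0.0, yll=0.0, cell_size=1.0)
        assert mask.is_land(1.0, 0.5)
        assert not mask.is_land(1.0001, 0.5)

    def test_outside_coverage_raises(self, coastal_mask):
        with pytest.raises(ValueError, match="coverage"):
            coastal_mask.is_land(100.0, 0.0)


class TestFilters:
    def test_all_ocean_track_unchanged(self, coastal_mask):
        track, _ = ms.simulate_track(
            n_points=80, outlier_rate=0, land_rate=0, classZ_rate=0, seed=3
        )
        kept, removed = filter_land(track, coastal_mask)
        assert len(removed) == 0 and len(kept) == len(track)

    def test_land_filter_removes_exactly_planted_points(self, coastal_mask):
        track, truth = ms.simulate_track(
            n_points=300, mask=coastal_mask, outlier_rate=0, classZ_rate=0, seed=5
        )
        kept, removed = filter_land(track, coastal_mask)
        idx = {id(p): i for i, p in enumerate(track.points)}
        assert sorted(idx[id(p)] for p in removed) == truth.outlier_labels["land"]

    def test_speed_boundary_is_strict(self):
        # exactly 10 km in 1 h: NOT over the threshold, kept
        lat = 10.0 / (2 * math.pi * EARTH_RADIUS_KM / 360)
        t = make_track([(0, 0.0, 0.0), (60, 0.0, lat)])
        kept, removed = filter_speed(t, vmax_kmh=10.0)
        assert len(kept) == 2 and not removed

    def test_speed_filter_removes_single_teleport(self):
        t = make_track([(0, 0, 0), (15, 0.01, 0), (30, 1.0, 0), (45, 0.03, 0)])
        kept, removed = filter_speed(t, vmax_kmh=10.0)
        assert [p.lon for p in removed] == [1.0]
        assert len(kept) == 3

    def test_speed_filter_keeps_constant_slow_track(self):
        track, _ = ms.simulate_track(
            n_points=100, outlier_rate=0, land_rate=0, classZ_rate=0,
            base_speed_kmh=5.0, seed=1,
        )
        kept, removed = filter_speed(track)
        assert not removed

    def test_zero_time_gap_drops_later_duplicate(self):
        t = make_track([(0, 0, 0), (15, 0.01, 0), (15, 0.02, 0)])
        kept, removed = filter_speed(t)
        assert len(kept) == 2 and len(removed) == 1
        assert removed[0].lon == 0.02

    def test_class_filter(self):
        t = make_track([(0, 0, 0), (15, 0.01, 0, "Z"), (30, 0.02, 0, "B")])
        kept, removed = filter_class(t)
        assert [p.loc_class for p in removed] == ["Z"]
        kept2, removed2 = filter_class(t, excluded=set())
        assert not removed2 and len(kept2) == 3

    def test_pipeline_report_matches_planted_truth(self, coastal_mask):
        track, truth = ms.simulate_track(
            n_points=400, mask=coastal_mask, classZ_rate=0.01, seed=8
        )
        cleaned, report = apply_filter_pipeline(track, mask=coastal_mask)
        assert report.n_input == 400
        assert report.n_removed_land == len(truth.outlier_labels["land"])
        assert report.n_removed_speed == len(truth.outlier_labels["speed"])
        assert report.n_removed_class == len(truth.outlier_labels["classZ"])
        assert report.n_output == len(cleaned)
        fr = report.fractions()
        assert fr["land"] == pytest.approx(report.n_removed_land / 400)

    def test_filters_idempotent(self, coastal_mask):
        track, _ = ms.simulate_track(n_points=300, mask=coastal_mask, seed=2)
        once, _ = apply_filter_pipeline(track, mask=coastal_mask)
        twice, rep2 = apply_filter_pipeline(once, mask=coastal_mask)
        assert rep2.n_removed_land == rep2.n_removed_speed == rep2.n_removed_class == 0
        assert len(twice) == len(once)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_speed_filter_invariants_on_random_tracks(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        lon = np.cumsum(rng.normal(0, 0.02, size=n))
        lat = np.cumsum(rng.normal(0, 0.02, size=n)) * 0.5
        t = make_track([(15 * i, lon[i], lat[i]) for i in range(n)])
        kept, removed = filter_speed(t, vmax_kmh=10.0)
        assert kept.points[0] == t.points[0]  # first point always retained
        for a, b in zip(kept.points, kept.points[1:]):
            dt_h = (b.timestamp - a.timestamp).total_seconds() / 3600
            speed = haversine_km((a.lon, a.lat), (b.lon, b.lat)) / dt_h
            assert speed <= 10.0 + 1e-9


class TestSummaries:
    def test_two_point_arithmetic(self):
        lat = 48.0 / (2 * math.pi * EARTH_RADIUS_KM / 360)
        t = make_track([(0, 0.0, 0.0), (24 * 60, 0.0, lat)])
        s = summarize_track(t)
        assert s.n_loc == 2
        assert s.duration_days == pytest.approx(1.0)
        assert s.distance_km == pytest.approx(48.0, rel=1e-6)
        assert s.speed_mean_kmh == pytest.approx(2.0, rel=1e-6)
        assert s.speed_sd_kmh is None

    def test_constant_velocity_has_zero_speed_sd(self):
        step = 0.01
        t = make_track([(15 * i, step * i, 0.0) for i in range(20)])
        s = summarize_track(t)
        assert s.speed_sd_kmh == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_resummation(self, coastal_mask):
        track, _ = ms.simulate_track(n_points=150, mask=coastal_mask, seed=4)
        s = summarize_track(track)
        pts = track.points
        dist = sum(
            haversine_km((a.lon, a.lat), (b.lon, b.lat))
            for a, b in zip(pts, pts[1:])
        )
        assert s.distance_km == pytest.approx(dist, rel=1e-12)
        assert s.n_loc == len(pts)
        assert s.duration_days == pytest.approx(
            (pts[-1].timestamp - pts[0].timestamp).total_seconds() / 86400
        )

    def test_collinear_intermediate_point_preserves_distance(self):
        t_direct = make_track([(0, 0.0, 0.0), (120, 2.0, 0.0)])
        t_split = make_track([(0, 0.0, 0.0), (60, 1.0, 0.0), (120, 2.0, 0.0)])
        assert summarize_track(t_split).distance_km == pytest.approx(
            summarize_track(t_direct).distance_km, rel=1e-6
        )

    def test_single_point_track(self):
        t = make_track([(0, 0.0, 0.0)])
        s = summarize_track(t)
        assert s.n_loc == 1 and s.distance_km == 0.0
        assert s.speed_mean_kmh is None

    def test_cohort_reproduces_published_footer(self):
        df = ms.datasets.load_migrant_summaries()
        cohort = summarize_cohort(df)
        assert cohort.loc["mean", "n_loc"] == pytest.approx(515, abs=0.5)
        assert cohort.loc["sd", "n_loc"] == pytest.approx(349, abs=0.5)
        assert cohort.loc["mean", "distance_km"] == pytest.approx(4394, abs=1)
        assert cohort.loc["sd", "distance_km"] == pytest.approx(1964, abs=1)
        assert cohort.loc["sd", "duration_days"] == pytest.approx(79, abs=0.5)

    def test_identical_tracks_have_zero_sd(self):
        s = ms.TrackSummary("a", 10, 1.0, 5.0, 2.0, 0.1)
        s2 = ms.TrackSummary("b", 10, 1.0, 5.0, 2.0, 0.1)
        cohort = summarize_cohort([s, s2])
        assert (cohort.loc["sd"] == 0).all()

    def test_cohort_needs_two_tracks(self):
        with pytest.raises(ValueError):
            summarize_cohort([ms.TrackSummary("a", 10, 1.0, 5.0, 2.0, 0.1)])


class TestTrackIO:
    def test_round_trip(self, coastal_mask, tmp_path):
        track, _ = ms.simulate_track(n_points=50, mask=coastal_mask, seed=6)
        path = tmp_path / "t.csv"
        write_tracks([track], path)
        back = read_tracks(path)
        assert len(back) == 1
        assert len(back[0]) == 50
        assert back[0].points[0].lon == pytest.approx(track.points[0].lon)
        assert back[0].points[0].timestamp == track.points[0].timestamp

    def test_ingestion_sorts_and_deduplicates(self, tmp_path):
        rows = (
            "track_id,timestamp,lon,lat,loc_class,source\n"
            "T1,2015-06-01T01:00:00Z,-61.0,14.5,G,GPS\n"
            "T1,2015-06-01T00:00:00Z,-61.1,14.4,G,GPS\n"
            "T1,2015-06-01T00:00:00Z,-61.1,14.4,G,GPS\n"
        )
        path = tmp_path / "t.csv"
        path.write_text(rows)
        (track,) = read_tracks(path)
        assert len(track) == 2
        assert track.points[0].lon == -61.1

    def test_coordinate_bounds_validated(self):
        with pytest.raises(ValueError):
            TrackPoint("T1", pd.Timestamp("2015-06-01T00:00:00Z"), 200.0, 0.0)
        with pytest.raises(ValueError):
            TrackPoint("T1", pd.Timestamp("2015-06-01T00:00:00Z"), 0.0, 95.0)
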