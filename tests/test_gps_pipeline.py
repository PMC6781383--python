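"""Speed filter, stay-point detection and stage splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tripwalk.config import DAY_S, PipelineConfig, WorldParams
from tripwalk.errors import OrderingError
from tripwalk.geo import LocalProjection, haversine_m, polyline_length_m
from tripwalk.gps_pipeline import (detect_visits, filter_low_speed, raw_daily_distance,
                                   split_stages)

from conftest import PROJ


def _track(xy_m, t=None) -> pd.DataFrame:
    """Point stream from local-meter coordinates (5-s cadence by default)."""
    xy_m = np.asarray(xy_m, float)
    lonlat = PROJ.to_lonlat(xy_m)
    if t is None:
        t = 5.0 * np.arange(len(xy_m))
    return pd.DataFrame({"t": np.asarray(t, float), "lon": lonlat[:, 0], "lat": lonlat[:, 1]})


def _reference_filter(points: pd.DataFrame, threshold_kmh: float,
                      anchor_reset_s: float) -> list[int]:
    """Independent single-pass re-statement of the retention rule."""
    t = points["t"].to_numpy()
    lon = points["lon"].to_numpy()
    lat = points["lat"].to_numpy()
    kept = [0]
    for i in range(1, len(t)):
        j = kept[-1]
        dt = t[i] - t[j]
        v = 3.6 * float(haversine_m(lon[j], lat[j], lon[i], lat[i])) / dt
        if v >= threshold_kmh or dt > anchor_reset_s:
            kept.append(i)
    return kept


class TestFilterLowSpeed:
    def test_stationary_track_keeps_only_first_point(self):
        pts = _track(np.zeros((40, 2)))
        out = filter_low_speed(pts, 1.0)
        assert len(out) == 1
        assert out["t"].iloc[0] == pts["t"].iloc[0]

    def test_default_threshold_is_one_kmh(self):
        assert PipelineConfig().speed_threshold_kmh == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_independent_reference_on_random_tracks(self, seed):
        rng = np.random.default_rng(seed)
        xy = np.cumsum(rng.normal(0, 4, size=(50, 2)), axis=0)
        pts = _track(xy)
        out = filter_low_speed(pts, 1.0)
        ref = _reference_filter(pts, 1.0, 300.0)
        assert list(out["t"]) == list(pts["t"].iloc[ref])

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        steps = rng.normal(0, 3, size=(n, 2))
        dt = rng.choice([5.0, 30.0, 400.0], size=n)
        pts = _track(np.cumsum(steps, axis=0), t=np.cumsum(dt))
        once = filter_low_speed(pts, 1.0)
        twice = filter_low_speed(once.drop(columns="speed_kmh"), 1.0)
        pd.testing.assert_frame_equal(once, twice)

    def test_unsorted_input_raises(self):
        pts = _track(np.zeros((3, 2)), t=[0.0, 10.0, 5.0])
        with pytest.raises(OrderingError):
            filter_low_speed(pts)


def _cluster(center_xy, n, spread=5.0, seed=0):
    rng = np.random.default_rng(seed)
    return np.asarray(center_xy) + rng.normal(0, spread, size=(n, 2))


class TestDetectVisits:
    def test_single_cluster_is_one_visit_no_moves(self):
        pts = _track(_cluster((0, 0), 200, spread=8.0), t=60.0 * np.arange(200))
        segs = detect_visits(pts, 300.0, 50.0)
        assert [s.kind for s in segs] == ["visit"]

    def test_two_clusters_joined_by_run(self):
        a = _cluster((0, 0), 30, seed=1)
        run = np.column_stack([np.linspace(30, 970, 40), np.zeros(40)])
        b = _cluster((1000, 0), 30, seed=2)
        t = np.concatenate([30 * np.arange(30),
                            900 + 5 * np.arange(40),
                            1100 + 30 * np.arange(30)])
        pts = _track(np.vstack([a, run, b]), t=t)
        segs = detect_visits(pts, 300.0, 50.0)
        kinds = [s.kind for s in segs]
        assert kinds == ["visit", "move", "visit"]

    def test_visit_count_matches_ground_truth_without_artefacts(self, noise_free_study):
        """Detected visits equal the diary's contiguous stays (overnight home
        stays span midnight, so per-day diary visits merge at day joins)."""
        for p in noise_free_study.participants:
            visits = [v for day in p.diary.days for v in day.visits]
            stays = 1
            for prev, cur in zip(visits, visits[1:]):
                if not (prev.end == cur.start and np.allclose(prev.location, cur.location)):
                    stays += 1
            detected = sum(1 for s in p.segments if s.kind == "visit")
            assert detected == stays

    def test_segments_tile_observed_span(self, noisy_study):
        for p in noisy_study.participants:
            segs = sorted(p.segments, key=lambda s: s.start)
            assert segs, "no segments detected"
            for a, b in zip(segs[:-1], segs[1:]):
                assert a.end == b.start
            t = p.filtered["t"].to_numpy()
            assert segs[0].start == t[0] and segs[-1].end == t[-1]

    @pytest.mark.parametrize("dwells", [(300.0, 600.0), (300.0, 1200.0)])
    def test_raising_dwell_never_increases_visit_count(self, noisy_study, dwells):
        lo, hi = dwells
        p = noisy_study.participants[0]
        n_lo = sum(1 for s in detect_visits(p.filtered, lo, 50.0) if s.kind == "visit")
        n_hi = sum(1 for s in detect_visits(p.filtered, hi, 50.0) if s.kind == "visit")
        assert n_hi <= n_lo


class TestSplitStages:
    def _move(self, noisy_study=None):
        # constant 20 km/h eastward run, far from any station
        v = 20 / 3.6
        t = 5.0 * np.arange(120)
        xy = np.column_stack([40_000 + v * t, 40_000 + np.zeros_like(t)])
        pts = _track(xy, t=t)
        return detect_visits(pts, 300.0, 50.0)

    def test_constant_speed_track_returned_unsplit(self):
        from tripwalk.gps_pipeline import CandidateSegment
        v = 20 / 3.6
        t = 5.0 * np.arange(120)
        xy = np.column_stack([v * t, np.zeros_like(t)])
        lonlat = PROJ.to_lonlat(xy)
        move = CandidateSegment("move", 0.0, 600.0,
                                points=np.column_stack([t, lonlat]), n_points=len(t))
        out = split_stages(move, None, PipelineConfig())
        assert len(out) == 1

    def test_walk_then_vehicle_splits_near_true_boundary(self):
        from tripwalk.gps_pipeline import CandidateSegment
        cfg = PipelineConfig()
        t = 5.0 * np.arange(240)
        speed = np.where(t < 600, 4.0 / 3.6, 30.0 / 3.6)
        x = np.concatenate([[0.0], np.cumsum(speed[:-1] * 5.0)])
        lonlat = PROJ.to_lonlat(np.column_stack([x, np.zeros_like(x)]))
        move = CandidateSegment("move", 0.0, 1200.0,
                                points=np.column_stack([t, lonlat]), n_points=len(t))
        out = split_stages(move, None, cfg)
        assert len(out) == 2
        window_s = cfg.smooth_window * 5.0
        assert abs(out[1].start - 600.0) <= window_s

    def test_partition_is_exact(self, noisy_study):
        cfg = PipelineConfig()
        for p in noisy_study.participants[:3]:
            for seg in p.segments:
                if seg.kind != "move":
                    continue
                parts = split_stages(seg, noisy_study.network, cfg)
                assert parts[0].start == seg.start
                assert parts[-1].end == seg.end
                for a, b in zip(parts[:-1], parts[1:]):
                    assert a.end == b.start
                assert sum(s.duration_s for s in parts) == pytest.approx(seg.duration_s)


class TestRawDailyDistance:
    def test_two_points_one_km(self):
        pts = _track([[0, 0], [1000, 0]], t=[0.0, 600.0])
        d = raw_daily_distance(pts)
        assert d.loc[0] == pytest.approx(1000.0, rel=1e-6)

    def test_closed_triangle_three_km(self):
        tri = [[0, 0], [1000, 0], [500, 866.0254], [0, 0]]
        # equilateral-ish triangle in local meters; use exact leg sums instead
        pts = _track(tri, t=[0.0, 60.0, 120.0, 180.0])
        xy = pts[["lon", "lat"]].to_numpy()
        expected = polyline_length_m(xy)
        assert raw_daily_distance(pts).loc[0] == pytest.approx(expected)
        assert expected == pytest.approx(3000.0, rel=1e-3)

    def test_raw_exceeds_survey_with_pseudo_ambulation(self, artefact_no_dropout_study):
        per_day = artefact_no_dropout_study.distances.per_day
        assert (per_day["quasi_raw_km"] > per_day["survey_km"]).all()
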