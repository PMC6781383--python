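"""Reconciliation, shortest-path recreation, track cleaning, distances."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tripwalk.config import DAY_S, PipelineConfig, WorldParams
from tripwalk.errors import IdentityError
from tripwalk.geo import polyline_length_m
from tripwalk.network import StreetGrid
from tripwalk.pipeline import process_participant, run_study
from tripwalk.survey_correction import (RecallModel, clean_track, reconcile,
                                        shortest_path_itinerary, surveyed_day_accounting)
from tripwalk.synthetic_world import generate_world

from conftest import PROJ, straight_polyline


@pytest.fixture(scope="module")
def grid():
    return StreetGrid(WorldParams())


class TestShortestPathItinerary:
    def test_same_endpoint_gives_single_point(self, grid):
        p = grid.node_lonlat((2, 3))
        poly = shortest_path_itinerary(p, p, grid)
        assert len(poly) == 1
        assert polyline_length_m(poly) == 0.0

    def test_opposite_corners_of_3x3_patch(self, grid):
        a = grid.node_lonlat((0, 0))
        b = grid.node_lonlat((2, 2))
        poly = shortest_path_itinerary(a, b, grid)
        assert len(poly) == 5  # 4 unit edges
        assert polyline_length_m(poly) == pytest.approx(4 * grid.spacing_m, rel=1e-4)

    def test_matches_exhaustive_search_on_small_grid(self, grid):
        """Brute force: enumerate every simple path on a 5x5 node patch."""

        def exhaustive_shortest(a, b):
            best = [np.inf]

            def dfs(node, seen, length):
                if length >= best[0]:
                    return
                if node == b:
                    best[0] = length
                    return
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    nb = (node[0] + di, node[1] + dj)
                    if 0 <= nb[0] <= 4 and 0 <= nb[1] <= 4 and nb not in seen:
                        dfs(nb, seen | {nb}, length + 1)

            dfs(a, {a}, 0)
            return best[0]

        rng = np.random.default_rng(5)
        nodes = list(itertools.product(range(5), range(5)))
        for _ in range(20):
            a, b = nodes[rng.integers(len(nodes))], nodes[rng.integers(len(nodes))]
            poly = shortest_path_itinerary(grid.node_lonlat(a), grid.node_lonlat(b), grid)
            assert len(poly) - 1 == abs(a[0] - b[0]) + abs(a[1] - b[1])
            assert len(poly) - 1 == exhaustive_shortest(a, b)


class TestCleanTrack:
    def test_artefact_free_track_unchanged(self):
        truth = straight_polyline(1000.0, n=11)
        out = clean_track(truth.copy(), truth, 60.0)
        np.testing.assert_allclose(out, truth)

    def test_injected_loop_removed_within_five_percent(self):
        truth = straight_polyline(2000.0, n=41)
        track = truth.copy()
        # 500-m artefact loop: excursions 250 m off-corridor mid-track
        loop_xy = PROJ.to_xy(track[18:23]) + np.array([0.0, 250.0])
        track[18:23] = PROJ.to_lonlat(loop_xy)
        assert polyline_length_m(track) > polyline_length_m(truth) + 400
        cleaned = clean_track(track, truth, 60.0)
        assert abs(polyline_length_m(cleaned) - polyline_length_m(truth)) \
            <= 0.05 * polyline_length_m(truth)

    def test_all_artefact_track_substituted_wholesale(self):
        truth = straight_polyline(1000.0, n=5)
        off = PROJ.to_lonlat(PROJ.to_xy(truth) + np.array([0.0, 5000.0]))
        out = clean_track(off, truth, 60.0)
        np.testing.assert_allclose(out, truth)


def _participant(world, pipe, seed, n_days=2):
    world.sensor.seed = seed
    network, diaries = generate_world(world, 1, n_days)
    grid = StreetGrid(world)
    return process_participant(diaries[0], network, grid, world, pipe), network, grid


class TestReconcile:
    def test_reconcile_is_idempotent_on_its_own_output(self):
        world = WorldParams()
        world.sensor = world.sensor.noise_free()
        pipe = PipelineConfig()
        p, network, grid = _participant(world, pipe, 31)
        again = reconcile(p.timetable, p.diary, RecallModel(1.0, 0.0), grid, pipe)
        assert len(again) == len(p.timetable)
        for a, b in zip(again, p.timetable):
            assert (a.kind, a.start, a.end, a.mode, a.trip_id) == \
                (b.kind, b.start, b.end, b.mode, b.trip_id)
            assert a.length_m == pytest.approx(b.length_m, abs=1e-6)
            assert a.source == "confirmed"

    def test_identity_mismatch_raises(self):
        world = WorldParams()
        world.sensor = world.sensor.noise_free()
        pipe = PipelineConfig()
        p, network, grid = _participant(world, pipe, 31)
        other = p.diary
        other_diary = type(other)("OTHER", other.zone, other.home, other.home_node,
                                  other.prior, other.days)
        with pytest.raises(IdentityError):
            reconcile(p.segments, other_diary, RecallModel(), grid, pipe)

    def test_dropped_trip_recreated_with_full_recall(self):
        world = WorldParams()
        world.sensor = world.sensor.noise_free()
        world.sensor.dropout_prob = 1.0  # the receiver stayed home all week
        pipe = PipelineConfig()
        p, network, grid = _participant(world, pipe, 33)
        stages = [s for s in p.timetable if s.kind == "trip_stage"]
        assert stages, "recall should recreate the dropped trips"
        assert all(s.source == "recreated" for s in stages)
        truth_trips = [t for day in p.diary.days for t in day.trips]
        assert len({s.trip_id for s in stages}) == len(truth_trips)
        # recreated length close to truth: grid shortest paths share the
        # Manhattan metric with the itineraries they stand in for
        total = sum(s.length_m for s in stages)
        truth_total = sum(t.distance_m for t in truth_trips)
        assert total == pytest.approx(truth_total, rel=0.05)

    def test_forgotten_trip_becomes_extended_visit(self):
        world = WorldParams()
        world.sensor = world.sensor.noise_free()
        world.sensor.dropout_prob = 1.0
        pipe = PipelineConfig(recall_prob=0.0)
        p, network, grid = _participant(world, pipe, 33)
        kinds = {s.kind for s in p.timetable}
        assert kinds == {"visit"}
        for day_idx in {s.day for s in p.timetable}:
            segs = sorted([s for s in p.timetable if s.day == day_idx],
                          key=lambda s: s.start)
            assert segs[0].start == day_idx * DAY_S
            assert segs[-1].end == (day_idx + 1) * DAY_S
            for a, b in zip(segs[:-1], segs[1:]):
                assert a.end == b.start

    @pytest.mark.parametrize("noise_sd", [0.0, 30.0])
    def test_timetable_tiles_each_surveyed_day(self, noise_sd):
        world = WorldParams()
        pipe = PipelineConfig(recall_noise_sd_s=noise_sd)
        p, network, grid = _participant(world, pipe, 35)
        for day_idx in {s.day for s in p.timetable}:
            segs = sorted([s for s in p.timetable if s.day == day_idx],
                          key=lambda s: s.start)
            total = sum(s.duration_s for s in segs)
            assert total == pytest.approx(DAY_S, abs=1e-6)
            for a, b in zip(segs[:-1], segs[1:]):
                assert a.end == pytest.approx(b.start, abs=1e-9)


class TestThreeWayDistances:
    def test_degenerate_world_all_three_agree(self):
        world = WorldParams()
        world.sensor = world.sensor.noise_free()
        res = run_study(world, PipelineConfig(), 3, 2, seed=41)
        per_day = res.distances.per_day
        # with no artefacts the three definitions differ only by fix-rate
        # discretization and stationary-drift residue: within ~6% + 150 m
        for col in ("algorithm_km", "survey_km"):
            diff = (per_day["quasi_raw_km"] - per_day[col]).abs()
            assert (diff <= 0.06 * per_day["quasi_raw_km"] + 0.15).all()

    def test_artefacts_on_order_raw_algorithm_survey(self, artefact_no_dropout_study):
        per_day = artefact_no_dropout_study.distances.per_day
        assert (per_day["quasi_raw_km"] > per_day["algorithm_km"]).all()
        assert (per_day["algorithm_km"] >= per_day["survey_km"] - 0.05).all()

    def test_dropouts_with_recall_raise_survey_above_algorithm(self):
        world = WorldParams()
        world.sensor = world.sensor.noise_free()
        world.sensor.dropout_prob = 0.5
        res = run_study(world, PipelineConfig(), 4, 3, seed=43)
        dropped_days = set()
        for p in res.participants:
            observed = {s.trip_id for s in p.timetable if s.source == "recreated"}
            for day in p.diary.days:
                if any(t.trip_id in observed for t in day.trips):
                    dropped_days.add((p.diary.participant_id, day.day))
        assert dropped_days, "expected some dropped trips at 50% dropout"
        per_day = res.distances.per_day
        affected = per_day.loc[list(dropped_days & set(per_day.index))]
        assert (affected["survey_km"] > affected["algorithm_km"]).all()


def test_surveyed_day_accounting_identity():
    ledger = surveyed_day_accounting(285, 7, 1784)
    assert ledger.scheduled_days == 1995
    assert ledger.excluded_days == 211
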