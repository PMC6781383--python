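"""Emulated prompted-recall mobility survey.

The phone survey walks the participant through the algorithm's output day by
day: spurious visits and trips are removed, missed trips are recalled and
recreated as shortest street-network paths, residual GPS artefacts are
cut out of trip itineraries, and modes and timestamps are validated.  The
result is the study's central data product: a timetable of visits, trip
stages and transfers that tiles each surveyed day exactly.

In emulation the participant's recall is played by the ground-truth diary,
moderated by a :class:`RecallModel` (recall probability, timestamp noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .config import DAY_S, PipelineConfig
from .errors import IdentityError, RoutingError
from .geo import LocalProjection, polyline_length_m
from .gps_pipeline import CandidateSegment
from .network import StreetGrid
from .synthetic_world import GroundTruthDiary, Stage, Transfer, Trip, Visit


@dataclass
class RecallModel:
    """Stands in for the participant on the phone."""

    recall_prob: float = 1.0
    timestamp_noise_sd_s: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.recall_prob <= 1.0:
            raise ValueError("recall_prob must lie in [0, 1]")
        if self.timestamp_noise_sd_s < 0:
            raise ValueError("timestamp_noise_sd_s must be >= 0")


@dataclass
class TimetableSegment:
    """One validated row of the final timetable."""

    participant_id: str
    day: int
    kind: str  # "visit" | "trip_stage" | "transfer"
    start: float
    end: float
    mode: str | None = None          # trip stages only (diary alphabet)
    polyline: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    location: np.ndarray | None = None
    trip_id: str | None = None
    source: str = "confirmed"        # confirmed | corrected | recreated
    steps: float = np.nan

    @property
    def length_m(self) -> float:
        return polyline_length_m(self.polyline) if self.kind == "trip_stage" else 0.0

    @property
    def duration_s(self) -> float:
        return self.end - self.start


def shortest_path_itinerary(origin, destination, grid: StreetGrid) -> np.ndarray:
    """Shortest street-grid path between two points, as a lon/lat polyline.

    Both endpoints are snapped to their nearest grid node; ties between
    equal-length paths are broken lexicographically on node order, so the
    itinerary is deterministic.
    """
    a, b = grid.snap(origin), grid.snap(destination)
    try:
        nodes = grid.dijkstra_path(a, b)
    except RoutingError:
        raise
    return grid.path_lonlat(nodes)


def clean_track(stage_polyline: np.ndarray, truth_polyline: np.ndarray,
                corridor_m: float = 60.0) -> np.ndarray:
    """Remove residual artefacts from a trip-stage track.

    Vertices farther than ``corridor_m`` from the reference itinerary are
    dropped (emulating manual deletion of artefact loops); if more than half
    the vertices are artefactual the reference itinerary is substituted
    wholesale (emulating a full manual redraw).
    """
    stage_polyline = np.asarray(stage_polyline, float)
    truth_polyline = np.asarray(truth_polyline, float)
    if len(stage_polyline) == 0 or len(truth_polyline) == 0:
        raise ValueError("clean_track requires non-empty polylines")
    lon_col = stage_polyline.shape[1] - 2  # accept (n,2) lon/lat or (n,3) t/lon/lat
    proj = LocalProjection(truth_polyline[0, -2], truth_polyline[0, -1])
    truth_xy = proj.to_xy(truth_polyline[:, -2:])
    ref = shapely.LineString(truth_xy) if len(truth_xy) > 1 else shapely.Point(truth_xy[0])
    pts = shapely.points(proj.to_xy(stage_polyline[:, lon_col:lon_col + 2]))
    dist = shapely.distance(ref, pts)
    keep = dist <= corridor_m
    if keep.sum() <= len(keep) // 2:
        return truth_polyline.copy()
    return stage_polyline[keep]


# ------------------------------------------------------------- reconciliation

def _observed_trips(algorithm_output, truth_pid: str):
    """Normalize algorithm output to (start, end, points) move records.

    Accepts the visit/move segments from the GPS pipeline, or a previously
    reconciled timetable (so reconciliation can be re-applied to its own
    output).
    """
    moves = []
    by_trip: dict = {}
    for seg in algorithm_output:
        pid = getattr(seg, "participant_id", "")
        if pid and truth_pid and pid != truth_pid:
            raise IdentityError(f"segment for {pid!r} reconciled against {truth_pid!r}")
        if isinstance(seg, CandidateSegment):
            if seg.kind == "move" and seg.points is not None and len(seg.points) >= 2:
                moves.append((seg.start, seg.end, seg.points))
        elif isinstance(seg, TimetableSegment):
            if seg.kind == "trip_stage":
                by_trip.setdefault(seg.trip_id, []).append(seg)
    for trip_id, stages in by_trip.items():
        stages.sort(key=lambda s: s.start)
        pts = []
        for s in stages:
            poly = np.asarray(s.polyline, float)
            if len(poly) == 0:
                continue
            ts = np.linspace(s.start, s.end, len(poly))
            pts.append(np.column_stack([ts, poly]))
        if pts:
            allpts = np.concatenate(pts)
            moves.append((stages[0].start, stages[-1].end, allpts))
    # merge moves that are directly adjacent in time (split across scores)
    moves.sort(key=lambda m: m[0])
    return moves


def _interval_iou(a0, a1, b0, b1) -> float:
    inter = max(0.0, min(a1, b1) - max(a0, b0))
    union = max(a1, b1) - min(a0, b0)
    return inter / union if union > 0 else 0.0


def _perturb_boundaries(segments: list[TimetableSegment], sd: float, rng) -> None:
    """Jitter internal boundaries jointly so the day still tiles exactly."""
    if sd <= 0 or len(segments) < 2:
        return
    bounds = [s.start for s in segments] + [segments[-1].end]
    for k in range(1, len(bounds) - 1):
        lo = bounds[k - 1]
        hi = bounds[k + 1]
        bounds[k] = float(np.clip(bounds[k] + rng.normal(0.0, sd), lo, hi))
    for k, seg in enumerate(segments):
        seg.start, seg.end = bounds[k], bounds[k + 1]


def reconcile(algorithm_output: list, truth: GroundTruthDiary,
              recall: RecallModel | None = None, grid: StreetGrid | None = None,
              config: PipelineConfig | None = None,
              rng: np.random.Generator | None = None) -> list[TimetableSegment]:
    """Confirm, correct, recreate: produce the validated timetable.

    * algorithm moves with no truth counterpart (interval IoU below the
      matching threshold against every truth trip) are removed;
    * truth trips with no algorithm counterpart are recalled with
      probability ``recall.recall_prob`` and recreated (walk/bike/car legs
      as shortest grid paths, transit legs along the line); an unrecalled
      trip is absorbed into the preceding visit;
    * matched trips keep the algorithm's geometry, sliced per truth stage
      and cleaned within the corridor, but take the surveyed (truth) modes
      and boundary timestamps, optionally perturbed by recall noise.
    """
    cfg = config or PipelineConfig()
    recall = recall or RecallModel(cfg.recall_prob, cfg.recall_noise_sd_s)
    rng = rng or np.random.default_rng(0)
    moves = _observed_trips(algorithm_output, truth.participant_id)

    timetable: list[TimetableSegment] = []
    for day in truth.days:
        day_segments: list[TimetableSegment] = []
        # greedy IoU matching of observed moves to this day's truth trips
        trips = day.trips
        match: dict[int, tuple] = {}
        cands = []
        for ti, trip in enumerate(trips):
            for move in moves:
                iou = _interval_iou(trip.start, trip.end, move[0], move[1])
                if iou >= cfg.iou_match_threshold:
                    cands.append((iou, ti, move))
        used = set()
        for iou, ti, move in sorted(cands, key=lambda c: -c[0]):
            if ti not in match and id(move) not in used:
                match[ti] = move
                used.add(id(move))

        pending_absorb = 0.0  # trip time swallowed by the preceding visit
        ti = -1
        for el in day.elements:
            if isinstance(el, Visit):
                seg = TimetableSegment(truth.participant_id, day.day, "visit",
                                       el.start, el.end, location=el.location.copy())
                if pending_absorb > 0:  # a forgotten trip extends this visit backwards
                    seg.start -= pending_absorb
                    seg.source = "corrected"
                    pending_absorb = 0.0
                day_segments.append(seg)
                continue
            ti += 1
            trip: Trip = el
            move = match.get(ti)
            if move is None and rng.random() >= recall.recall_prob:
                pending_absorb = trip.end - trip.start  # forgotten: extend next visit backwards
                continue
            for sub in trip.elements:
                if isinstance(sub, Transfer):
                    day_segments.append(TimetableSegment(
                        truth.participant_id, day.day, "transfer", sub.start, sub.end,
                        location=sub.location.copy(), trip_id=trip.trip_id,
                        source="confirmed" if move is not None else "recreated"))
                    continue
                sub: Stage
                if move is not None:
                    pts = move[2]
                    sel = (pts[:, 0] >= sub.start) & (pts[:, 0] <= sub.end)
                    sliced = pts[sel][:, 1:3]
                    if len(sliced) >= 2:
                        cleaned = clean_track(sliced, sub.polyline, cfg.clean_corridor_m)
                        substituted = len(cleaned) == len(sub.polyline) \
                            and np.array_equal(cleaned, sub.polyline)
                        poly = cleaned[:, -2:]
                        source = "corrected" if substituted else "confirmed"
                        if not substituted:
                            # manual complementation: anchor the itinerary at
                            # the validated stage endpoints (missing track
                            # heads/tails are completed during the survey)
                            if polyline_length_m(np.vstack([sub.polyline[0], poly[0]])) > 1.0:
                                poly = np.vstack([sub.polyline[0], poly])
                            if polyline_length_m(np.vstack([poly[-1], sub.polyline[-1]])) > 1.0:
                                poly = np.vstack([poly, sub.polyline[-1]])
                    else:
                        poly, source = sub.polyline.copy(), "corrected"
                else:
                    source = "recreated"
                    if grid is not None and sub.mode in ("walk", "bike_roller_skateboard",
                                                         "car_driver", "car_passenger"):
                        poly = shortest_path_itinerary(sub.polyline[0], sub.polyline[-1], grid)
                        poly = np.vstack([sub.polyline[0], poly, sub.polyline[-1]])
                    else:
                        poly = sub.polyline.copy()
                day_segments.append(TimetableSegment(
                    truth.participant_id, day.day, "trip_stage", sub.start, sub.end,
                    mode=sub.mode, polyline=poly, trip_id=trip.trip_id, source=source))
        _perturb_boundaries(day_segments, recall.timestamp_noise_sd_s, rng)
        timetable.extend(day_segments)
    return timetable


# --------------------------------------------------------- distance reporting

@dataclass
class ThreeWayDistanceReport:
    """Per participant-day distances under the three definitions, with the
    median and interdecile range of each across participant-days."""

    per_day: pd.DataFrame   # index (participant, day); km columns
    summary: pd.DataFrame   # rows median/p10/p90


def algorithm_daily_distance(segments: list[CandidateSegment]) -> pd.Series:
    """Algorithm-trip distance: summed move-polyline length per day."""
    rows: dict = {}
    for seg in segments:
        if seg.kind != "move" or seg.points is None:
            continue
        day = int(seg.start // DAY_S)
        rows[day] = rows.get(day, 0.0) + polyline_length_m(seg.points[:, 1:3])
    return pd.Series(rows, dtype=float).sort_index().rename("distance_m")


def survey_daily_distance(timetable: list[TimetableSegment]) -> pd.Series:
    """Survey-corrected distance: summed validated stage length per day."""
    rows: dict = {}
    for seg in timetable:
        if seg.kind == "trip_stage":
            rows[seg.day] = rows.get(seg.day, 0.0) + seg.length_m
    return pd.Series(rows, dtype=float).sort_index().rename("distance_m")


def three_way_distance_report(raw: pd.DataFrame, algorithm: pd.DataFrame,
                              survey: pd.DataFrame) -> ThreeWayDistanceReport:
    """Join the three per-day distance tables and summarize their spread.

    Each input has a (participant, day) index and a ``distance_m`` column;
    only participant-days present in all three enter the comparison.
    """
    per_day = pd.concat(
        {"quasi_raw_km": raw["distance_m"], "algorithm_km": algorithm["distance_m"],
         "survey_km": survey["distance_m"]}, axis=1, join="inner") / 1000.0
    summary = pd.DataFrame({
        "median": per_day.median(),
        "p10": per_day.quantile(0.10),
        "p90": per_day.quantile(0.90),
    }).T
    return ThreeWayDistanceReport(per_day, summary)


@dataclass
class SurveyedDayLedger:
    scheduled_days: int
    surveyed_days: int

    @property
    def excluded_days(self) -> int:
        return self.scheduled_days - self.surveyed_days


def surveyed_day_accounting(n_participants: int, days_per_participant: int,
                            surveyed_days: int) -> SurveyedDayLedger:
    """Scheduled-versus-surveyed day bookkeeping for a study wave."""
    return SurveyedDayLedger(n_participants * days_per_participant, surveyed_days)
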