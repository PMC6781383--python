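"""Algorithm-only GPS processing: speed filter, visit detection, stage split.

This is the sensor-only half of the measurement chain: it sees nothing but
timestamped fixes.  Its output (visits, moves, candidate unimodal stages) is
what the prompted-recall survey later confirms or corrects.

Point streams are pandas DataFrames with columns ``t`` (seconds), ``lon``,
``lat`` (WGS84 degrees); a ``speed_kmh`` column (speed relative to the
previously retained fix) is added by the filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import OrderingError
from .geo import haversine_m
from .network import TransitNetwork

POINT_COLS = ("t", "lon", "lat")


@dataclass
class CandidateSegment:
    """A detected visit or move with a half-open time interval.

    Moves carry their fixes as an (n, 3) array of (t, lon, lat); visits carry
    a single representative location (the cluster centroid).
    """

    kind: str  # "visit" | "move"
    start: float
    end: float
    participant_id: str = ""
    points: np.ndarray | None = None  # moves: (n, 3) t/lon/lat
    location: np.ndarray | None = None  # visits
    n_points: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return self.end - self.start

    @property
    def polyline(self) -> np.ndarray:
        if self.kind == "visit":
            return self.location[None, :]
        return self.points[:, 1:3]


def _check_sorted(t: np.ndarray) -> None:
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise OrderingError("timestamps must be strictly increasing")


def filter_low_speed(points: pd.DataFrame, threshold_kmh: float = 1.0,
                     anchor_reset_s: float = 300.0) -> pd.DataFrame:
    """Drop fixes slower than ``threshold_kmh`` relative to the last kept fix.

    This is the conventional first cleaning pass on logging-GPS streams: it
    removes stationary scatter while the wearer is at a place.  The first fix
    is always retained and speeds are recomputed against retained
    predecessors, so the operation is a single greedy pass (and idempotent).

    A fix more than ``anchor_reset_s`` after the retained predecessor is
    always kept: without this reset a long stationary spell makes the speed
    reference arbitrarily stale and would swallow the start of the next
    genuine movement.
    """
    t = points["t"].to_numpy(float)
    _check_sorted(t)
    if len(points) == 0:
        out = points.copy()
        out["speed_kmh"] = np.zeros(0)
        return out
    lon = points["lon"].to_numpy(float)
    lat = points["lat"].to_numpy(float)
    keep = [0]
    speeds = [0.0]
    last = 0
    for i in range(1, len(t)):
        dt = t[i] - t[last]
        d = haversine_m(lon[last], lat[last], lon[i], lat[i])
        v = 3.6 * d / dt
        if v >= threshold_kmh or dt > anchor_reset_s:
            keep.append(i)
            speeds.append(float(v))
            last = i
    out = points.iloc[keep].reset_index(drop=True).copy()
    out["speed_kmh"] = speeds
    return out


def _stay_clusters(t, lon, lat, dwell_min_s, radius_m):
    """Maximal runs of fixes staying within ``radius_m`` of their running
    centroid for at least ``dwell_min_s``; returns inclusive index pairs."""
    n = len(t)
    clusters = []
    i = 0
    while i < n - 1:
        cx, cy = lon[i], lat[i]
        j = i + 1
        while j < n:
            if t[j] - t[j - 1] > dwell_min_s:  # signal gap breaks any cluster
                break
            if haversine_m(cx, cy, lon[j], lat[j]) > radius_m:
                break
            m = j - i + 1
            cx += (lon[j] - cx) / m
            cy += (lat[j] - cy) / m
            j += 1
        if t[j - 1] - t[i] >= dwell_min_s:
            clusters.append((i, j - 1))
            i = j
        else:
            i += 1
    return clusters


def detect_visits(points: pd.DataFrame, dwell_min_s: float = 300.0,
                  radius_m: float = 50.0, participant_id: str = "") -> list[CandidateSegment]:
    """Stay-point detection: visits and the moves between them.

    Three rules beyond plain clustering reflect how raw streams behave:

    * a signal gap longer than ``dwell_min_s`` is itself a visit (the
      receiver stopped seeing the sky — or stayed home during a trip);
    * two consecutive visits whose centroids are within ``radius_m`` are
      merged, absorbing the intervening movement as pseudo-ambulation;
    * moves need at least 2 fixes, otherwise they are absorbed.

    The returned segments tile the observed time span exactly.
    """
    if len(points) == 0:
        return []
    t = points["t"].to_numpy(float)
    _check_sorted(t)
    lon = points["lon"].to_numpy(float)
    lat = points["lat"].to_numpy(float)
    n = len(t)

    clusters = _stay_clusters(t, lon, lat, dwell_min_s, radius_m)

    # insert gap-visits: index pairs (k, k+1) spanning a long silent interval
    events = [(i0, i1, "cluster") for i0, i1 in clusters]
    covered = np.zeros(n, bool)
    for i0, i1, _ in events:
        covered[i0:i1 + 1] = True
    for k in range(n - 1):
        if t[k + 1] - t[k] > dwell_min_s and not (covered[k] and covered[k + 1]):
            events.append((k, k + 1, "gap"))
    events.sort()

    # visit records: (first_idx, last_idx, centroid)
    visits = []
    for i0, i1, kind in events:
        if kind == "cluster":
            c = np.array([lon[i0:i1 + 1].mean(), lat[i0:i1 + 1].mean()])
            visits.append([i0, i1, c])
        else:
            visits.append([i0, i1, np.array([lon[i0], lat[i0]])])
    # merge overlapping/adjacent visits; also merge co-located consecutive
    # visits when the movement between them never leaves the pseudo-ambulation
    # envelope (a genuine out-and-back loop trip is preserved)
    envelope_m = 6.0 * radius_m
    merged: list[list] = []
    for v in visits:
        if merged:
            prev = merged[-1]
            overlap = v[0] <= prev[1] + 1
            near = haversine_m(prev[2][0], prev[2][1], v[2][0], v[2][1]) <= radius_m
            if near and not overlap:
                mid = slice(prev[1] + 1, v[0])
                if len(lon[mid]) and haversine_m(lon[mid], lat[mid],
                                                 prev[2][0], prev[2][1]).max() > envelope_m:
                    near = False
            if overlap or near:
                prev[1] = max(prev[1], v[1])
                prev[2] = np.array([lon[prev[0]:prev[1] + 1].mean(), lat[prev[0]:prev[1] + 1].mean()])
                continue
        merged.append(list(v))

    segments: list[CandidateSegment] = []

    def add_move(i0, i1, start, end):
        if i1 - i0 < 1 or end <= start:
            return False
        pts = np.column_stack([t[i0:i1 + 1], lon[i0:i1 + 1], lat[i0:i1 + 1]])
        segments.append(CandidateSegment("move", start, end, participant_id,
                                         points=pts, n_points=i1 - i0 + 1))
        return True

    cursor_idx, cursor_t = 0, t[0]
    for i0, i1, c in merged:
        if t[i0] > cursor_t:
            ok = add_move(cursor_idx, i0, cursor_t, t[i0])
            if not ok and segments and segments[-1].kind == "visit":
                segments[-1].end = t[i0]
        segments.append(CandidateSegment("visit", t[i0], t[i1], participant_id,
                                         location=c, n_points=i1 - i0 + 1))
        cursor_idx, cursor_t = i1, t[i1]
    if cursor_t < t[-1]:
        ok = add_move(cursor_idx, n - 1, cursor_t, t[-1])
        if not ok and segments and segments[-1].kind == "visit":
            segments[-1].end = t[-1]
    if not segments:  # a single all-day cluster
        return []
    # close final visit at the last observed fix
    if segments and segments[-1].kind == "visit":
        segments[-1].end = t[-1]
    return segments


def _smoothed_speeds(points: np.ndarray, window: int) -> np.ndarray:
    t, lon, lat = points[:, 0], points[:, 1], points[:, 2]
    v = np.zeros(len(t))
    if len(t) > 1:
        d = haversine_m(lon[:-1], lat[:-1], lon[1:], lat[1:])
        v[1:] = 3.6 * d / np.diff(t)
        v[0] = v[1]
    return pd.Series(v).rolling(window, center=True, min_periods=1).median().to_numpy()


def split_stages(move: CandidateSegment, network: TransitNetwork | None = None,
                 config: PipelineConfig | None = None) -> list[CandidateSegment]:
    """Split a move into candidate unimodal stages.

    Fix speeds are median-smoothed, classified into the walk band versus the
    vehicle bands, and the move is cut where the smoothed speed crosses the
    band boundary; runs shorter than ``min_stage_s`` are merged into their
    longer neighbour.  When a transit network is supplied, each cut is
    snapped to the nearby fix closest to a station within the snap radius
    (mode changes happen at stations).  The output intervals partition the
    input interval exactly.
    """
    cfg = config or PipelineConfig()
    pts = move.points
    if pts is None or len(pts) < 2:
        raise ValueError("split_stages requires a move with >= 2 fixes")
    v = _smoothed_speeds(pts, cfg.smooth_window)
    vehicle = v >= cfg.walk_speed_boundary_kmh

    # run-length encode, then merge short runs into the longer neighbour
    runs = []  # [start_idx, end_idx_exclusive, label]
    s = 0
    for k in range(1, len(vehicle) + 1):
        if k == len(vehicle) or vehicle[k] != vehicle[s]:
            runs.append([s, k, bool(vehicle[s])])
            s = k
    t = pts[:, 0]

    def run_dur(r):
        end_t = t[r[1]] if r[1] < len(t) else move.end
        return end_t - t[r[0]]

    changed = True
    while changed and len(runs) > 1:
        changed = False
        durs = [run_dur(r) for r in runs]
        k = int(np.argmin(durs))
        if durs[k] < cfg.min_stage_s:
            if k == 0:
                nb = 1
            elif k == len(runs) - 1:
                nb = k - 1
            else:
                nb = k - 1 if durs[k - 1] >= durs[k + 1] else k + 1
            lo, hi = min(k, nb), max(k, nb)
            runs[lo] = [runs[lo][0], runs[hi][1], runs[nb][2]]
            del runs[hi]
            changed = True

    cut_idx = [r[0] for r in runs[1:]]
    if network is not None and cut_idx:
        cut_idx = [_snap_cut(pts, c, network, cfg) for c in cut_idx]
        cut_idx = sorted(set(c for c in cut_idx if 0 < c < len(pts)))

    bounds = [0] + cut_idx + [len(pts) - 1]
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b <= a:
            continue
        start = t[a] if a > 0 else move.start
        end = t[b] if b < len(pts) - 1 else move.end
        seg = CandidateSegment("move", start, end, move.participant_id,
                               points=pts[a:b + 1], n_points=b - a + 1)
        seg.meta["median_speed_kmh"] = float(np.median(v[a:b + 1]))
        out.append(seg)
    return out


def _snap_cut(pts: np.ndarray, cut: int, network: TransitNetwork, cfg: PipelineConfig) -> int:
    lo, hi = max(1, cut - cfg.smooth_window // 2), min(len(pts) - 1, cut + cfg.smooth_window // 2 + 1)
    best, best_d = cut, np.inf
    for k in range(lo, hi):
        near = network.stations_near(pts[k, 1:3], cfg.station_snap_m)
        if near and near[0][2] < best_d:
            best, best_d = k, near[0][2]
    return best if np.isfinite(best_d) else cut


def raw_daily_distance(points: pd.DataFrame) -> pd.Series:
    """Quasi-raw distance per day: consecutive-fix haversine legs, summed by
    the day of each leg's starting fix (local-midnight day boundaries)."""
    t = points["t"].to_numpy(float)
    if len(t) < 2:
        return pd.Series(dtype=float, name="distance_m")
    lon = points["lon"].to_numpy(float)
    lat = points["lat"].to_numpy(float)
    d = haversine_m(lon[:-1], lat[:-1], lon[1:], lat[1:])
    day = np.floor(t[:-1] / 86400.0).astype(int)
    return pd.Series(d).groupby(day).sum().rename("distance_m")
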