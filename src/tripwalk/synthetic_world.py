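"""Synthetic region, participants, ground-truth diaries, and sensor streams.

The generator emulates the measurement setting of a week-long multi-sensor
mobility study in a dense European region: participants carry a GPS logger
(one fix every 5 s in motion) and a waist accelerometer over 7 days, and
their true activity-travel diary — visits to places alternating with
multimodal trips decomposed into unimodal stages separated by punctual
transfer episodes — is known exactly, so that algorithm and survey outputs
can be scored against it.

Artefact channels (all switchable) reproduce the failure modes that motivate
survey correction: stationary GPS scatter at places, pseudo-ambulation
bursts inflating raw distances, and whole-trip dropouts when the receiver is
left behind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DAY_S, DIARY_TO_ALGO, SensorConfig, TRANSIT_MODES, WorldParams, ZONES
from .errors import ConfigurationError
from .geo import cumulative_chainage_m, point_at_chainage, polyline_length_m
from .network import StreetGrid, TransitLine, TransitNetwork, build_transit_network

VM_MEAN = {  # vector-magnitude counts per minute while worn, by context
    "walk": 2800.0, "walk_pt_access": 2900.0, "bike_roller_skateboard": 1200.0,
    "vehicle": 120.0, "jogging": 6000.0, "dog_walking": 1500.0,
    "transfer": 500.0, "visit": 150.0,
}
VISIT_ZERO_VM_PROB = 0.2  # sedentary epochs with literally no counts


# ---------------------------------------------------------------- diary types

@dataclass
class Stage:
    """One unimodal trip stage with its polyline and timing.

    ``knots_t`` / ``knots_s`` give the time -> chainage schedule used by the
    GPS renderer (piecewise linear; transit rides pause at intermediate
    stations).  ``None`` means constant speed.
    """

    mode: str
    start: float
    end: float
    polyline: np.ndarray
    cadence_key: str
    knots_t: np.ndarray | None = None
    knots_s: np.ndarray | None = None

    @property
    def length_m(self) -> float:
        return polyline_length_m(self.polyline)

    @property
    def duration_s(self) -> float:
        return self.end - self.start


@dataclass
class Transfer:
    """Punctual change-of-mode episode: duration but zero mapped distance."""

    start: float
    end: float
    location: np.ndarray

    @property
    def duration_s(self) -> float:
        return self.end - self.start


@dataclass
class Visit:
    place_id: str
    location: np.ndarray
    start: float
    end: float


@dataclass
class Trip:
    """Ordered stages separated by transfers, between two visited places."""

    trip_id: str
    elements: list  # Stage, Transfer, Stage, ... (alternating, odd length)
    primary_mode: str  # the mode the generator drew from the mixture

    @property
    def start(self) -> float:
        return self.elements[0].start

    @property
    def end(self) -> float:
        return self.elements[-1].end

    @property
    def stages(self) -> list[Stage]:
        return [e for e in self.elements if isinstance(e, Stage)]

    @property
    def transfers(self) -> list[Transfer]:
        return [e for e in self.elements if isinstance(e, Transfer)]

    @property
    def distance_m(self) -> float:
        return sum(s.length_m for s in self.stages)


@dataclass
class DiaryDay:
    day: int
    elements: list  # Visit, Trip, Visit, ..., Visit (alternating)

    @property
    def trips(self) -> list[Trip]:
        return [e for e in self.elements if isinstance(e, Trip)]

    @property
    def visits(self) -> list[Visit]:
        return [e for e in self.elements if isinstance(e, Visit)]


@dataclass
class GroundTruthDiary:
    participant_id: str
    zone: str
    home: np.ndarray
    home_node: tuple
    prior: dict  # algorithm-mode habitual-use weights, normalized
    days: list[DiaryDay] = field(default_factory=list)

    def iter_segments(self):
        """Flat (day, kind, mode, start, end, trip_id, obj) records."""
        for day in self.days:
            trip_no = 0
            for el in day.elements:
                if isinstance(el, Visit):
                    yield (day.day, "visit", None, el.start, el.end, None, el)
                else:
                    trip_no += 1
                    for sub in el.elements:
                        if isinstance(sub, Stage):
                            yield (day.day, "trip_stage", sub.mode, sub.start, sub.end, el.trip_id, sub)
                        else:
                            yield (day.day, "transfer", None, sub.start, sub.end, el.trip_id, sub)


def validate_diary(diary: GroundTruthDiary) -> None:
    """Assert the diary invariants: tiling, alternation, shared endpoints."""
    for day in diary.days:
        t0, t1 = day.day * DAY_S, (day.day + 1) * DAY_S
        cursor = t0
        for k, el in enumerate(day.elements):
            expected_visit = k % 2 == 0
            assert isinstance(el, Visit) == expected_visit, "visit/trip alternation broken"
            start = el.start
            assert start == cursor, f"gap or overlap at t={cursor}"
            cursor = el.end
            if isinstance(el, Trip):
                assert len(el.elements) % 2 == 1
                sub_cursor = el.start
                for i, sub in enumerate(el.elements):
                    assert isinstance(sub, Stage) == (i % 2 == 0), "stage/transfer alternation broken"
                    assert sub.start == sub_cursor
                    sub_cursor = sub.end
                    if isinstance(sub, Transfer):
                        prev, nxt = el.elements[i - 1], el.elements[i + 1]
                        assert np.allclose(prev.polyline[-1], sub.location, atol=1e-9)
                        assert np.allclose(nxt.polyline[0], sub.location, atol=1e-9)
                assert sub_cursor == el.end
        assert isinstance(day.elements[0], Visit) and isinstance(day.elements[-1], Visit)
        assert np.allclose(day.elements[0].location, diary.home)
        assert np.allclose(day.elements[-1].location, diary.home)
        assert cursor == t1, "day does not tile to midnight"


# ----------------------------------------------------------- diary generation

class _DiaryBuilder:
    """Per-participant machinery; one rng stream per participant."""

    def __init__(self, params: WorldParams, grid: StreetGrid, network: TransitNetwork,
                 rng: np.random.Generator, pid: str, zone: str, home_node: tuple):
        self.p = params
        self.grid = grid
        self.net = network
        self.rng = rng
        self.pid = pid
        self.zone = zone
        self.home_node = home_node
        self.home = grid.node_lonlat(home_node)
        self.mix = params.mode_mix[zone]
        self._trip_counter = 0
        self._place_counter = 0

    # -- helpers -----------------------------------------------------------

    def _speed(self, mode: str) -> float:
        return self.p.speeds_kmh[mode] / 3.6

    def _stage(self, mode: str, start: float, coords: np.ndarray, cadence_key: str,
               speed_key: str | None = None) -> Stage:
        length = polyline_length_m(coords)
        v = self._speed(speed_key or mode)
        dur = max(1.0, round(length / v))
        return Stage(mode, start, start + dur, np.asarray(coords, float), cadence_key)

    def _ride_stage(self, mode: str, start: float, line: TransitLine, i0: int, i1: int,
                    dwell_s: float) -> Stage:
        step = 1 if i1 > i0 else -1
        coords = line.stations[np.arange(i0, i1 + step, step)].copy()
        chain = cumulative_chainage_m(coords)
        length = chain[-1]
        n_int = len(coords) - 2
        cruise = length / self._speed(mode)
        dur = round(cruise + max(0, n_int) * dwell_s)
        # piecewise schedule: cruise between stations, pause at each stop
        kt, ks = [start], [0.0]
        t = start
        for k in range(len(coords) - 1):
            t += (chain[k + 1] - chain[k]) / length * cruise
            kt.append(t)
            ks.append(chain[k + 1])
            if k < len(coords) - 2 and dwell_s > 0:
                t += dwell_s
                kt.append(t)
                ks.append(chain[k + 1])
        kt = np.asarray(kt)
        kt = start + (kt - start) * (dur / max(kt[-1] - start, 1e-9))  # exact end time
        return Stage(mode, start, start + dur, coords, "vehicle", kt, np.asarray(ks))

    def _transfer(self, start: float, location) -> Transfer:
        dur = float(self.rng.integers(0, 181))
        return Transfer(start, start + dur, np.asarray(location, float))

    def _walk_coords(self, a_node: tuple, b_lonlat=None, b_node: tuple | None = None) -> np.ndarray:
        """Walk polyline from node ``a`` to node ``b`` or off-grid point ``b_lonlat``."""
        if b_node is None:
            b_node = self.grid.snap(b_lonlat)
        coords = self.grid.path_lonlat(self.grid.l_path(a_node, b_node))
        if b_lonlat is not None and not np.allclose(coords[-1], b_lonlat):
            coords = np.vstack([coords, b_lonlat])
        return coords

    def _random_dest(self, origin: tuple, lo: int, hi: int) -> tuple:
        """Grid node at Manhattan distance in [lo, hi] steps from origin."""
        for _ in range(64):
            d = int(self.rng.integers(lo, hi + 1))
            di = int(self.rng.integers(-d, d + 1))
            dj = d - abs(di)
            if self.rng.random() < 0.5:
                dj = -dj
            node = (origin[0] + di, origin[1] + dj)
            if self.grid.in_bounds(node) and node != origin:
                return node
        return origin  # pathological grids only

    def _board_line(self, origin_lonlat, mode: str):
        cands = self.net.stations_near(origin_lonlat, self.p.access_max_m[mode], mode=mode)
        return cands[0][:2] if cands else None

    # -- trip constructors -------------------------------------------------

    def _pt_elements(self, start: float, origin_node: tuple, mode: str,
                     dest_node: tuple | None):
        """walk -> transfer -> ride [-> transfer -> feeder bus] -> transfer -> walk."""
        origin = self.grid.node_lonlat(origin_node)
        hit = self._board_line(origin, mode)
        if hit is None:
            return None
        line, i_board = hit
        if dest_node is not None:
            d = [float(polyline_length_m(np.vstack([s, self.grid.node_lonlat(dest_node)])))
                 for s in line.stations]
            i_alight = int(np.argmin(d))
            if abs(i_alight - i_board) < 1 or d[i_alight] > self.p.access_max_m[mode]:
                return None
        else:
            lo, hi = max(0, i_board - 8), min(len(line.stations) - 1, i_board + 8)
            choices = [i for i in range(lo, hi + 1) if abs(i - i_board) >= 2]
            if not choices:
                return None
            i_alight = int(self.rng.choice(choices))
        board_xy = line.stations[i_board]
        alight_xy = line.stations[i_alight]

        els = []
        access = self._stage("walk", start, self._walk_coords(origin_node, b_lonlat=board_xy),
                             "walk_pt_access", speed_key="walk_pt_access")
        els.append(access)
        els.append(self._transfer(access.end, board_xy))
        ride = self._ride_stage(mode, els[-1].end, line, i_board, i_alight,
                                self.p.sensor.station_dwell_s)
        els.append(ride)
        cursor_xy = alight_xy
        cursor_node = self.grid.snap(alight_xy)

        if (mode in ("metro", "suburban_train", "tramway") and dest_node is None
                and self.rng.random() < self.p.feeder_bus_prob):
            feeder = self.net.stations_near(alight_xy, 600.0, mode="bus")
            if feeder:
                bline, j_board, _ = feeder[0]
                lo, hi = max(0, j_board - 5), min(len(bline.stations) - 1, j_board + 5)
                choices = [j for j in range(lo, hi + 1) if abs(j - j_board) >= 2]
                if choices:
                    j_alight = int(self.rng.choice(choices))
                    els.append(self._transfer(ride.end, alight_xy))
                    link = self._stage("walk", els[-1].end,
                                       np.vstack([alight_xy, bline.stations[j_board]]),
                                       "walk_pt_access", speed_key="walk_pt_access")
                    els.append(link)
                    els.append(self._transfer(link.end, bline.stations[j_board]))
                    bus = self._ride_stage("bus", els[-1].end, bline, j_board, j_alight,
                                           self.p.sensor.station_dwell_s)
                    els.append(bus)
                    cursor_xy = bline.stations[j_alight]
                    cursor_node = self.grid.snap(cursor_xy)

        els.append(self._transfer(els[-1].end, cursor_xy))
        if dest_node is None:
            egress_steps = 2 if mode == "suburban_train" else 1
            dest_node = self._random_dest(cursor_node, 0, egress_steps)
        coords = np.vstack([cursor_xy, self.grid.path_lonlat(
            self.grid.l_path(cursor_node, dest_node))])
        egress = self._stage("walk", els[-1].end, coords, "walk_pt_access",
                             speed_key="walk_pt_access")
        els.append(egress)
        return els, dest_node

    def make_trip(self, start: float, origin_node: tuple, mode: str,
                  dest_node: tuple | None = None):
        """Build one trip; returns (Trip, dest_node) or None if infeasible."""
        if mode in TRANSIT_MODES:
            built = self._pt_elements(start, origin_node, mode, dest_node)
            if built is None:
                return None
            els, dest_node = built
        elif mode in ("jogging", "dog_walking"):
            out = self._random_dest(origin_node, 2, 4)
            nodes = self.grid.l_path(origin_node, out)
            coords = self.grid.path_lonlat(nodes + nodes[-2::-1])
            els = [self._stage(mode, start, coords, mode)]
            dest_node = origin_node
        else:
            ranges = {"walk": (1, 3), "bike_roller_skateboard": (2, 7),
                      "car_driver": (4, 24), "car_passenger": (4, 24),
                      "ski_chairlift": (2, 6)}
            lo, hi = ranges.get(mode, (2, 8))
            if dest_node is None:
                dest_node = self._random_dest(origin_node, lo, hi)
            coords = self.grid.path_lonlat(self.grid.l_path(origin_node, dest_node))
            key = {"walk": "walk", "bike_roller_skateboard": "bike_roller_skateboard"}.get(mode, "vehicle")
            els = [self._stage(mode, start, coords, key)]
        self._trip_counter += 1
        trip = Trip(f"{self.pid}-T{self._trip_counter:04d}", els, mode)
        return trip, dest_node

    def _draw_mode(self) -> str:
        modes = list(self.mix)
        probs = np.array([self.mix[m] for m in modes])
        return str(self.rng.choice(modes, p=probs / probs.sum()))

    def _reverse_trip(self, trip: Trip, start: float) -> Trip:
        """The same itinerary travelled back, with fresh transfer durations."""
        els = []
        t = start
        for sub in trip.elements[::-1]:
            if isinstance(sub, Stage):
                dur = sub.end - sub.start
                st = Stage(sub.mode, t, t + dur, sub.polyline[::-1].copy(), sub.cadence_key)
                if sub.knots_t is not None:
                    st.knots_t = t + (sub.end - sub.knots_t[::-1])
                    st.knots_s = sub.knots_s[-1] - sub.knots_s[::-1]
                els.append(st)
                t += dur
            else:
                tr = self._transfer(t, sub.location)
                els.append(tr)
                t = tr.end
        self._trip_counter += 1
        return Trip(f"{self.pid}-T{self._trip_counter:04d}", els, trip.primary_mode)

    def _draw_stay(self, after: float, t0: float) -> float:
        stay = float(np.clip(round(self.rng.lognormal(np.log(3600), 0.6)), 600, 4 * 3600))
        if after + stay > t0 + 20.5 * 3600:
            stay = max(600.0, t0 + 20.5 * 3600 - after)
        return stay

    def build_day(self, day: int) -> DiaryDay:
        t0 = day * DAY_S
        elements = []
        loc_node = self.home_node
        dep = t0 + float(np.clip(round(self.rng.normal(8.5 * 3600, 3600)), 6 * 3600, 11 * 3600))
        n_trips = int(np.clip(self.rng.poisson(self.p.trips_per_day_mean), 1, 9))

        def add_visit(start, end, node):
            if elements and isinstance(elements[-1], Visit) \
                    and np.allclose(elements[-1].location, self.grid.node_lonlat(node)):
                elements[-1].end = end  # consecutive stays at one place merge
                return
            self._place_counter += 1
            pid = "home" if node == self.home_node else f"{self.pid}-P{self._place_counter:04d}"
            elements.append(Visit(pid, self.grid.node_lonlat(node), start, end))

        add_visit(t0, dep, loc_node)
        trips_made = 0
        while trips_made < n_trips and dep < t0 + 19.5 * 3600:
            # rejection-redraw keeps realized shares close to the mixture even
            # when a drawn transit mode is infeasible from this origin
            built = None
            for _attempt in range(8):
                built = self.make_trip(dep, loc_node, self._draw_mode())
                if built is not None:
                    break
            if built is None:
                built = self.make_trip(dep, loc_node, "car_driver")
            trip, new_node = built
            if trip.end > t0 + 20 * 3600:
                break
            origin_node = loc_node
            elements.append(trip)
            trips_made += 1
            loc_node = new_node
            stay = self._draw_stay(trip.end, t0)
            add_visit(trip.end, trip.end + stay, loc_node)
            dep = trip.end + stay
            # out-and-back tours: most excursions return the way they came
            if loc_node != origin_node and trips_made < n_trips \
                    and self.rng.random() < 0.6:
                back = self._reverse_trip(trip, dep)
                if back.end <= t0 + 21 * 3600:
                    elements.append(back)
                    trips_made += 1
                    loc_node = origin_node
                    stay = self._draw_stay(back.end, t0)
                    add_visit(back.end, back.end + stay, loc_node)
                    dep = back.end + stay
        if loc_node != self.home_node:
            trip, loc_node = self._return_home(dep, loc_node)
            elements.append(trip)
            dep = trip.end
        add_visit(dep, t0 + DAY_S, self.home_node)
        return DiaryDay(day, elements)

    def _return_home(self, dep: float, loc_node: tuple):
        """Trip back to the residence, drawn from the mixture restricted to
        the modes feasible for this origin-home pair."""
        home_dist = abs(loc_node[0] - self.home_node[0]) + abs(loc_node[1] - self.home_node[1])
        feasible = ["car_driver", "car_passenger"]
        if home_dist <= 3:
            feasible.append("walk")
        if home_dist <= 7:
            feasible.append("bike_roller_skateboard")
        feasible.extend(m for m in TRANSIT_MODES if self.mix.get(m, 0) > 0)
        weights = np.array([self.mix.get(m, 0.0) for m in feasible])
        if weights.sum() <= 0:
            feasible, weights = ["car_driver"], np.array([1.0])
        mode = str(self.rng.choice(feasible, p=weights / weights.sum()))
        built = self.make_trip(dep, loc_node, mode, dest_node=self.home_node)
        if built is None:
            built = self.make_trip(dep, loc_node, "car_driver", dest_node=self.home_node)
        return built


def generate_world(config: WorldParams, n_participants: int, n_days: int):
    """Generate the region and one ground-truth diary per participant.

    Reproducible for a fixed ``config.sensor.seed``: each participant draws
    from an independent stream keyed by (seed, participant index), so adding
    participants never perturbs existing diaries.
    """
    if n_participants < 1 or n_days < 1:
        raise ConfigurationError("n_participants and n_days must be >= 1")
    config.validate()
    grid = StreetGrid(config)
    network = build_transit_network(config)

    # nodes per zone ring, ordered deterministically
    zone_nodes = {z: [] for z in ZONES}
    for i in grid.node_range:
        for j in grid.node_range:
            r = float(np.hypot(i * grid.spacing_m, j * grid.spacing_m))
            if r <= config.core_radius_m:
                zone_nodes["core_city"].append((i, j))
            elif r <= config.close_radius_m:
                zone_nodes["close_suburb"].append((i, j))
            elif r <= config.half_extent_m - grid.spacing_m:
                zone_nodes["far_suburb"].append((i, j))

    shares = np.array([config.zone_shares[z] for z in ZONES])
    diaries = []
    for p in range(n_participants):
        rng = np.random.default_rng([config.sensor.seed, p])
        zone = ZONES[int(rng.choice(len(ZONES), p=shares / shares.sum()))]
        home_node = zone_nodes[zone][int(rng.integers(len(zone_nodes[zone])))]
        prior = {}
        for mode, w in config.mode_mix[zone].items():
            algo = DIARY_TO_ALGO.get(mode)
            if algo is not None:
                prior[algo] = prior.get(algo, 0.0) + w
        total = sum(prior.values())
        prior = {m: w / total for m, w in prior.items()}
        builder = _DiaryBuilder(config, grid, network, rng, f"P{p:03d}", zone, home_node)
        diary = GroundTruthDiary(builder.pid, zone, builder.home, home_node, prior)
        diary.days = [builder.build_day(d) for d in range(n_days)]
        diaries.append(diary)
    return network, diaries


# ------------------------------------------------------------- GPS rendering

def _pid_key(participant_id: str) -> int:
    """Stable (non-salted) integer key for a participant id."""
    import zlib

    return zlib.crc32(participant_id.encode()) % (2 ** 31)

def _ar1_jitter(rng, n: int, sd_m: float, rho: float = 0.98) -> np.ndarray:
    """Autocorrelated 2-D position noise with stationary sd ``sd_m``."""
    if sd_m == 0 or n == 0:
        return np.zeros((n, 2))
    innov_sd = sd_m * np.sqrt(1 - rho ** 2)
    eps = rng.normal(0.0, innov_sd, size=(n, 2))
    out = np.empty((n, 2))
    out[0] = rng.normal(0.0, sd_m, size=2)
    for k in range(1, n):
        out[k] = rho * out[k - 1] + eps[k]
    return out


def _stage_points(stage: Stage, period: float) -> tuple[np.ndarray, np.ndarray]:
    ts = np.arange(stage.start, stage.end, period)
    coords = np.asarray(stage.polyline, float)
    chain = cumulative_chainage_m(coords)
    if stage.knots_t is not None:
        s = np.interp(ts, stage.knots_t, stage.knots_s)
    else:
        frac = (ts - stage.start) / max(stage.end - stage.start, 1e-9)
        s = frac * chain[-1]
    return ts, point_at_chainage(coords, chain, s)


def render_gps(diary: GroundTruthDiary, config: SensorConfig) -> pd.DataFrame:
    """Render the GPS point stream for one participant.

    Columns ``t`` (s), ``lon``, ``lat``.  In-trip fixes are sampled every
    ``gps_period_s`` along the stage polylines (with station dwells for
    transit rides); visits emit sparse, autocorrelated scatter around the
    place, plus an optional pseudo-ambulation burst; with probability
    ``dropout_prob`` an entire trip leaves no trace.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _pid_key(diary.participant_id), 7])
    proj_scale = np.pi * 6_371_000.0 / 180.0
    lat0 = float(diary.home[1])
    m2deg = np.array([1.0 / (proj_scale * np.cos(np.radians(lat0))), 1.0 / proj_scale])

    ts_all, xy_all = [], []

    def emit(ts, coords, noise_m=None):
        if len(ts) == 0:
            return
        coords = np.atleast_2d(coords)
        if noise_m is not None:
            coords = coords + noise_m * m2deg
        ts_all.append(np.asarray(ts, float))
        xy_all.append(coords)

    for day in diary.days:
        for el in day.elements:
            if isinstance(el, Visit):
                ts = np.arange(el.start, el.end, config.visit_period_s)
                noise = _ar1_jitter(rng, len(ts), config.jitter_visit_sd_m)
                if config.jitter_visit_sd_m > 0 and len(ts):
                    # occasional multipath jumps: the scatter that passes the
                    # low-speed filter and inflates raw indoor distances
                    jump = rng.random(len(ts)) < 0.05
                    noise[jump] += rng.normal(0.0, 2.0 * config.jitter_visit_sd_m,
                                              size=(int(jump.sum()), 2))
                emit(ts, np.repeat(el.location[None, :], len(ts), axis=0), noise)
                dur = el.end - el.start
                if dur >= 900 and rng.random() < config.pseudo_ambulation_rate:
                    # burst: mean-reverting walk around the place at GPS rate
                    blen = float(min(rng.uniform(600, 2400), dur - 60))
                    b0 = el.start + float(rng.uniform(0, dur - blen))
                    bts = np.arange(b0, b0 + blen, config.gps_period_s)
                    wander = _ar1_jitter(rng, len(bts), config.burst_sd_m,
                                         rho=float(np.sqrt(max(0.0, 1 - (config.burst_step_sd_m / max(config.burst_sd_m, 1e-9)) ** 2))))
                    emit(bts, np.repeat(el.location[None, :], len(bts), axis=0), wander)
            else:  # Trip
                if rng.random() < config.dropout_prob:
                    continue
                for sub in el.elements:
                    if isinstance(sub, Stage):
                        visible = sub.mode != "metro" or rng.random() < config.underground_visible_prob
                        ts, coords = _stage_points(sub, config.gps_period_s)
                        if not visible:  # tunnel: the receiver sees no sky
                            continue
                        noise = _ar1_jitter(rng, len(ts), config.jitter_trip_sd_m, rho=0.9) \
                            if config.jitter_trip_sd_m > 0 else None
                        emit(ts, coords, noise)
                    else:
                        ts = np.arange(sub.start, sub.end, config.gps_period_s)
                        noise = _ar1_jitter(rng, len(ts), config.jitter_visit_sd_m)
                        emit(ts, np.repeat(sub.location[None, :], len(ts), axis=0), noise)

    if not ts_all:
        return pd.DataFrame(columns=["t", "lon", "lat"])
    t = np.concatenate(ts_all)
    xy = np.concatenate(xy_all)
    order = np.argsort(t, kind="stable")
    t, xy = t[order], xy[order]
    keep = np.concatenate([[True], np.diff(t) > 0])  # dedupe boundary fixes
    return pd.DataFrame({"t": t[keep], "lon": xy[keep, 0], "lat": xy[keep, 1]})


# ------------------------------------------------------- accelerometer stream

def render_accel(diary: GroundTruthDiary, config: SensorConfig) -> pd.DataFrame:
    """Render the accelerometer epoch stream: columns ``t``, ``vm``, ``steps``.

    The epoch grid is aligned to midnight and gapless over the diary span.
    Per-epoch steps are drawn from the cadence model of the diary context at
    the epoch midpoint, truncated at zero; epochs outside the wear window
    carry zero counts and zero steps.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _pid_key(diary.participant_id), 11])
    n_days = len(diary.days)
    epoch = float(config.accel_epoch_s)
    t = np.arange(0.0, n_days * DAY_S, epoch)
    mid = t + epoch / 2.0

    # context label per epoch via the diary's segment intervals
    starts, keys = [], []
    for _, kind, _, s0, _, _, obj in diary.iter_segments():
        starts.append(s0)
        if kind == "visit":
            keys.append("visit")
        elif kind == "transfer":
            keys.append("transfer")
        else:
            keys.append(obj.cadence_key)
    starts = np.asarray(starts)
    order = np.argsort(starts, kind="stable")
    starts = starts[order]
    keys = [keys[i] for i in order]
    idx = np.clip(np.searchsorted(starts, mid, side="right") - 1, 0, len(keys) - 1)

    tod = mid % DAY_S
    worn = (tod >= config.wear_start_s) & (tod < config.wear_end_s)

    minutes = epoch / 60.0
    steps = np.zeros(len(t))
    vm = np.zeros(len(t))
    for k, key in enumerate(keys):
        sel = worn & (idx == k)
        n = int(sel.sum())
        if n == 0:
            continue
        mean, sd = config.cadence.get(key, config.cadence["vehicle"])
        draw = rng.normal(mean * minutes, sd * np.sqrt(minutes), size=n) if sd > 0 else np.full(n, mean * minutes)
        steps[sel] = np.maximum(0.0, np.round(draw))
        base = VM_MEAN.get(key, VM_MEAN["vehicle"]) * minutes
        v = np.maximum(0.0, rng.normal(base, 0.25 * base + 1.0, size=n))
        if key == "visit":
            v[rng.random(n) < VISIT_ZERO_VM_PROB] = 0.0
        vm[sel] = np.round(v)
    return pd.DataFrame({"t": t, "vm": vm, "steps": steps})
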