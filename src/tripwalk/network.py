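"""Street grid and transit network of the synthetic region.

The street network is a rectangular grid graph; grid shortest paths stand in
for "shortest street network path" when trips missed by the GPS receiver are
recreated during the survey.  The transit network is a set of lines, each an
ordered sequence of stations; transfer hubs are modelled as co-located
distinct stations (every station belongs to exactly one line).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .config import TRANSIT_MODES, WorldParams
from .errors import ConfigurationError, RoutingError
from .geo import LocalProjection, haversine_m


@dataclass
class TransitLine:
    line_id: str
    mode: str
    stations: np.ndarray  # (n, 2) lon/lat, ordered along the line

    def __post_init__(self):
        self.stations = np.asarray(self.stations, dtype=float)
        if self.mode not in TRANSIT_MODES:
            raise ConfigurationError(f"unknown transit mode {self.mode!r}")
        if len(self.stations) < 2:
            raise ConfigurationError(f"line {self.line_id} has fewer than 2 stations")


@dataclass
class TransitNetwork:
    lines: list[TransitLine] = field(default_factory=list)

    def __post_init__(self):
        self._all = None

    def _station_table(self):
        # flat arrays (lonlat, line index, station index) built lazily
        if self._all is None:
            coords, line_idx, stat_idx = [], [], []
            for li, line in enumerate(self.lines):
                coords.append(line.stations)
                line_idx.extend([li] * len(line.stations))
                stat_idx.extend(range(len(line.stations)))
            self._all = (
                np.concatenate(coords) if coords else np.zeros((0, 2)),
                np.array(line_idx, dtype=int),
                np.array(stat_idx, dtype=int),
            )
        return self._all

    def stations_near(self, lonlat, radius_m: float, mode: str | None = None):
        """Stations within ``radius_m`` of a point: list of (line, station_idx, dist_m)."""
        coords, line_idx, stat_idx = self._station_table()
        if len(coords) == 0:
            return []
        d = haversine_m(coords[:, 0], coords[:, 1], lonlat[0], lonlat[1])
        out = []
        for k in np.flatnonzero(d <= radius_m):
            line = self.lines[line_idx[k]]
            if mode is None or line.mode == mode:
                out.append((line, int(stat_idx[k]), float(d[k])))
        out.sort(key=lambda t: (t[2], t[0].line_id, t[1]))
        return out

    def modes_near(self, lonlat, radius_m: float) -> set[str]:
        return {line.mode for line, _, _ in self.stations_near(lonlat, radius_m)}


class StreetGrid:
    """Rectangular street grid in lon/lat with unit spacing in meters.

    Nodes are integer pairs ``(i, j)``; the projection maps them to lon/lat.
    """

    def __init__(self, params: WorldParams):
        self.spacing_m = float(params.grid_spacing_m)
        self.n_half = int(params.half_extent_m // params.grid_spacing_m)
        self.proj = LocalProjection(params.lon0, params.lat0)

    @property
    def node_range(self):
        return range(-self.n_half, self.n_half + 1)

    def in_bounds(self, node) -> bool:
        i, j = node
        return -self.n_half <= i <= self.n_half and -self.n_half <= j <= self.n_half

    def node_xy(self, node) -> np.ndarray:
        return np.array([node[0] * self.spacing_m, node[1] * self.spacing_m])

    def node_lonlat(self, node) -> np.ndarray:
        return self.proj.to_lonlat(self.node_xy(node))[0]

    def snap(self, lonlat) -> tuple[int, int]:
        """Nearest grid node to a lon/lat point (clipped to the grid)."""
        xy = self.proj.to_xy(lonlat)[0]
        i = int(np.clip(round(xy[0] / self.spacing_m), -self.n_half, self.n_half))
        j = int(np.clip(round(xy[1] / self.spacing_m), -self.n_half, self.n_half))
        return (i, j)

    def neighbors(self, node):
        i, j = node
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb = (i + di, j + dj)
            if self.in_bounds(nb):
                yield nb

    def l_path(self, a, b) -> list[tuple[int, int]]:
        """Deterministic Manhattan path: along x first, then along y.

        Used by the diary generator: a valid grid shortest path with the
        fewest turns, which keeps GPS corner-cutting error negligible.
        """
        path = [a]
        i, j = a
        step = 1 if b[0] >= i else -1
        while i != b[0]:
            i += step
            path.append((i, j))
        step = 1 if b[1] >= j else -1
        while j != b[1]:
            j += step
            path.append((i, j))
        return path

    def dijkstra_path(self, a, b) -> list[tuple[int, int]]:
        """Grid shortest path with lexicographic node-order tie-breaking."""
        if not (self.in_bounds(a) and self.in_bounds(b)):
            raise RoutingError(f"endpoint off the grid: {a} -> {b}")
        if a == b:
            return [a]
        # uniform edge weights: ties broken by the lexicographic rank of the
        # full predecessor chain, encoded via (dist, node) heap ordering
        dist = {a: 0}
        prev = {}
        heap = [(0, a)]
        while heap:
            d, node = heapq.heappop(heap)
            if node == b:
                break
            if d > dist.get(node, np.inf):
                continue
            for nb in self.neighbors(node):
                nd = d + 1
                if nd < dist.get(nb, np.inf) or (nd == dist.get(nb, np.inf) and node < prev.get(nb, (np.inf,))):
                    dist[nb] = nd
                    prev[nb] = node
                    heapq.heappush(heap, (nd, nb))
        if b not in dist:
            raise RoutingError(f"no grid path between {a} and {b}")
        path = [b]
        while path[-1] != a:
            path.append(prev[path[-1]])
        return path[::-1]

    def path_lonlat(self, nodes) -> np.ndarray:
        return np.array([self.node_lonlat(n) for n in nodes])


def build_transit_network(params: WorldParams) -> TransitNetwork:
    """Lay out transit lines over the region.

    Metro and tramway serve the core and close suburb; suburban trains cross
    the whole region; buses run both central and peripheral corridors.
    Station spacing per mode follows urban practice (metro ~600 m, tram
    ~500 m, bus ~450 m, suburban train ~2500 m).  Stations are offset 60 m
    off the street axis so that walk legs to stations are never degenerate.
    """
    proj = LocalProjection(params.lon0, params.lat0)
    e = params.half_extent_m - params.grid_spacing_m

    def line(line_id, mode, axis, offset, lo, hi, spacing, perp=60.0):
        s = np.arange(lo, hi + 1e-6, spacing)
        xy = np.empty((len(s), 2))
        if axis == "x":  # line runs along x at height `offset`
            xy[:, 0], xy[:, 1] = s, offset + perp
        else:
            xy[:, 0], xy[:, 1] = offset + perp, s
        return TransitLine(line_id, mode, proj.to_lonlat(xy))

    lines = [
        # metro: two diameters plus two chords in the core/close ring
        line("M1", "metro", "x", 0.0, -5000, 5000, 600),
        line("M2", "metro", "y", 0.0, -5000, 5000, 600),
        line("M3", "metro", "x", 2000.0, -4000, 4000, 600),
        line("M4", "metro", "y", -2000.0, -4000, 4000, 600),
        # tramway: tangential lines in the close suburb
        line("T1", "tramway", "x", 5000.0, -7000, 7000, 500),
        line("T2", "tramway", "x", -5000.0, -7000, 7000, 500),
        line("T3", "tramway", "y", 5000.0, -7000, 7000, 500),
        # suburban trains: full-extent diameters, offset from the metro axes
        line("S1", "suburban_train", "x", -300.0, -e, e, 2500),
        line("S2", "suburban_train", "y", -300.0, -e, e, 2500),
        # buses: central and peripheral corridors (the far suburb's local PT)
        line("B1", "bus", "x", 3000.0, -e, e, 450),
        line("B2", "bus", "x", -3000.0, -e, e, 450),
        line("B3", "bus", "y", 3000.0, -e, e, 450),
        line("B4", "bus", "y", -3000.0, -e, e, 450),
        line("B5", "bus", "x", 9000.0, -e, e, 450),
        line("B6", "bus", "x", -9000.0, -e, e, 450),
        line("B7", "bus", "y", 9000.0, -e, e, 450),
        line("B8", "bus", "y", -9000.0, -e, e, 450),
    ]
    return TransitNetwork(lines)
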