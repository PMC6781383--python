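"""Geodesic helpers: haversine distances, polyline lengths, local projection.

All coordinates are (lon, lat) in degrees, WGS84.  Distances are great-circle
(haversine) on consecutive vertices, which is the convention used throughout
the package; for the small (~25 km) study regions this agrees with projected
distances to well below GPS noise.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in meters between two points (vectorized)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def polyline_length_m(coords) -> float:
    """Length of a (n, 2) lon/lat polyline, summing consecutive haversine legs."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or len(coords) < 2:
        return 0.0
    return float(np.sum(haversine_m(coords[:-1, 0], coords[:-1, 1], coords[1:, 0], coords[1:, 1])))


def cumulative_chainage_m(coords) -> np.ndarray:
    """Cumulative distance along a polyline, starting at 0."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) == 0:
        return np.zeros(0)
    legs = haversine_m(coords[:-1, 0], coords[:-1, 1], coords[1:, 0], coords[1:, 1])
    return np.concatenate([[0.0], np.cumsum(legs)])


def point_at_chainage(coords: np.ndarray, chain: np.ndarray, s) -> np.ndarray:
    """Interpolate point(s) at distance ``s`` along a polyline.

    ``chain`` is the precomputed cumulative chainage.  ``s`` is clipped to the
    polyline extent.  Returns an (m, 2) array of lon/lat.
    """
    s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, chain[-1] if len(chain) else 0.0)
    if len(coords) == 1:
        return np.repeat(coords, len(s), axis=0)
    idx = np.clip(np.searchsorted(chain, s, side="right") - 1, 0, len(coords) - 2)
    seg_len = chain[idx + 1] - chain[idx]
    frac = np.where(seg_len > 0, (s - chain[idx]) / np.where(seg_len > 0, seg_len, 1.0), 0.0)
    return coords[idx] + frac[:, None] * (coords[idx + 1] - coords[idx])


class LocalProjection:
    """Equirectangular projection to local meters around a reference point.

    Adequate for sub-degree regions; used for grid construction, jitter
    injection and point-to-polyline distances, never for reported distances
    (those are haversine).
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._m_per_deg_lat = np.pi * EARTH_RADIUS_M / 180.0
        self._m_per_deg_lon = self._m_per_deg_lat * np.cos(np.radians(lat0))

    def to_xy(self, lonlat) -> np.ndarray:
        lonlat = np.atleast_2d(np.asarray(lonlat, dtype=float))
        out = np.empty_like(lonlat)
        out[:, 0] = (lonlat[:, 0] - self.lon0) * self._m_per_deg_lon
        out[:, 1] = (lonlat[:, 1] - self.lat0) * self._m_per_deg_lat
        return out

    def to_lonlat(self, xy) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        out = np.empty_like(xy)
        out[:, 0] = self.lon0 + xy[:, 0] / self._m_per_deg_lon
        out[:, 1] = self.lat0 + xy[:, 1] / self._m_per_deg_lat
        return out
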