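"""Readers and writers for the package's exchange formats.

GPS points travel as CSV (ISO-8601 timestamp, lat, lon) and GPX 1.1;
accelerometer epochs as CSV (timestamp, vm, steps); diaries, networks and
candidate segments as GeoJSON FeatureCollections; and the validated
timetable as the central CSV exchange format of the repository.

Internal clocks count seconds from a fixed simulation epoch (a Monday
midnight); the writers convert to timestamps, the readers convert back.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET

import numpy as np
import pandas as pd

from .gps_pipeline import CandidateSegment
from .network import TransitNetwork
from .survey_correction import TimetableSegment
from .synthetic_world import GroundTruthDiary, Stage, Visit

SIM_EPOCH = pd.Timestamp("2014-01-06T00:00:00Z")


def to_timestamp(t_s) -> pd.Series:
    return SIM_EPOCH + pd.to_timedelta(np.asarray(t_s, float), unit="s")


def from_timestamp(ts) -> np.ndarray:
    return (pd.to_datetime(ts, utc=True, format="ISO8601") - SIM_EPOCH).total_seconds() \
        if not isinstance(ts, pd.Series) else \
        (pd.to_datetime(ts, utc=True, format="ISO8601") - SIM_EPOCH).dt.total_seconds().to_numpy()


# ------------------------------------------------------------------- GPS

def write_gps_csv(points: pd.DataFrame, path) -> None:
    out = pd.DataFrame({"timestamp": to_timestamp(points["t"]).map(lambda x: x.isoformat()),
                        "lat": points["lat"], "lon": points["lon"]})
    out.to_csv(path, index=False)


def read_gps_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return pd.DataFrame({"t": from_timestamp(df["timestamp"]),
                         "lon": df["lon"], "lat": df["lat"]})


def write_gpx(points: pd.DataFrame, path, name: str = "track") -> None:
    """Minimal GPX 1.1 writer: one track, one segment."""
    gpx = ET.Element("gpx", version="1.1", creator="tripwalk",
                     xmlns="http://www.topografix.com/GPX/1/1")
    trk = ET.SubElement(gpx, "trk")
    ET.SubElement(trk, "name").text = name
    seg = ET.SubElement(trk, "trkseg")
    stamps = to_timestamp(points["t"])
    for (_, row), ts in zip(points.iterrows(), stamps):
        pt = ET.SubElement(seg, "trkpt", lat=f"{row['lat']:.7f}", lon=f"{row['lon']:.7f}")
        ET.SubElement(pt, "time").text = ts.isoformat()
    ET.ElementTree(gpx).write(path, xml_declaration=True, encoding="unicode")


def read_gpx(path) -> pd.DataFrame:
    ns = {"g": "http://www.topografix.com/GPX/1/1"}
    root = ET.parse(path).getroot()
    rows = []
    for pt in root.iterfind(".//g:trkpt", ns):
        ts = pt.findtext("g:time", namespaces=ns)
        rows.append((float(from_timestamp(ts)), float(pt.get("lon")), float(pt.get("lat"))))
    return pd.DataFrame(rows, columns=["t", "lon", "lat"])


# --------------------------------------------------------------- accel

def write_accel_csv(epochs: pd.DataFrame, path) -> None:
    out = pd.DataFrame({"timestamp": to_timestamp(epochs["t"]).map(lambda x: x.isoformat()),
                        "vm": epochs["vm"].astype(int), "steps": epochs["steps"].astype(int)})
    out.to_csv(path, index=False)


def read_accel_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return pd.DataFrame({"t": from_timestamp(df["timestamp"]),
                         "vm": df["vm"].astype(float), "steps": df["steps"].astype(float)})


# ------------------------------------------------------------ timetable

def timetable_frame(timetable: list[TimetableSegment]) -> pd.DataFrame:
    rows = []
    for s in timetable:
        rows.append({
            "participant": s.participant_id, "day": s.day, "kind": s.kind,
            "trip_id": s.trip_id, "mode": s.mode,
            "start": to_timestamp([s.start])[0].isoformat(),
            "end": to_timestamp([s.end])[0].isoformat(),
            "length_m": round(s.length_m, 1), "steps": s.steps, "source": s.source,
        })
    return pd.DataFrame(rows)


def write_timetable_csv(timetable: list[TimetableSegment], path) -> None:
    timetable_frame(timetable).to_csv(path, index=False)


# -------------------------------------------------------------- GeoJSON

def _feature(geometry: dict, props: dict) -> dict:
    return {"type": "Feature", "geometry": geometry, "properties": props}


def _iso(t: float) -> str:
    return to_timestamp([t])[0].isoformat()


def diary_to_geojson(diary: GroundTruthDiary) -> dict:
    feats = []
    for day, kind, mode, s0, s1, trip_id, obj in diary.iter_segments():
        props = {"kind": kind, "mode": mode, "start": _iso(s0), "end": _iso(s1),
                 "trip_id": trip_id, "day": day}
        if isinstance(obj, Stage):
            geom = {"type": "LineString", "coordinates": np.asarray(obj.polyline).tolist()}
        elif isinstance(obj, Visit):
            geom = {"type": "Point", "coordinates": list(map(float, obj.location))}
        else:
            geom = {"type": "Point", "coordinates": list(map(float, obj.location))}
        feats.append(_feature(geom, props))
    return {"type": "FeatureCollection", "features": feats,
            "properties": {"participant": diary.participant_id, "zone": diary.zone}}


def network_to_geojson(network: TransitNetwork) -> dict:
    feats = []
    for line in network.lines:
        feats.append(_feature(
            {"type": "LineString", "coordinates": line.stations.tolist()},
            {"kind": "transit_line", "mode": line.mode, "line_id": line.line_id}))
        for k, st in enumerate(line.stations):
            feats.append(_feature({"type": "Point", "coordinates": list(map(float, st))},
                                  {"kind": "station", "mode": line.mode,
                                   "line_id": line.line_id, "idx": k}))
    return {"type": "FeatureCollection", "features": feats}


def segments_to_geojson(segments: list[CandidateSegment]) -> dict:
    feats = []
    for seg in segments:
        props = {"kind": seg.kind, "start": _iso(seg.start), "end": _iso(seg.end),
                 "n_points": seg.n_points}
        if seg.kind == "visit":
            geom = {"type": "Point", "coordinates": list(map(float, seg.location))}
        else:
            geom = {"type": "LineString", "coordinates": seg.points[:, 1:3].tolist()}
        feats.append(_feature(geom, props))
    return {"type": "FeatureCollection", "features": feats}


def write_geojson(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh)
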