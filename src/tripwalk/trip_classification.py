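"""Trip assembly, crude/detailed mode classification, analytic exclusions.

A trip's class is driven by its non-walking stages: all-walk trips are
``entirely_walked``; a single distinct non-walking mode (at the granularity
of the scheme in force) gives that mode's class; two or more distinct
non-walking modes make a ``multi_mode`` trip.  Walking stages never create
multi-modality, which is why the detailed scheme (which splits public
transport into four classes and the car into driver/passenger) finds more
multi-mode trips than the crude one.

Non-transport movement is excluded before analysis: a ski/chairlift stage
voids its whole movement sequence; a jogging or dog-walking stage is cut
out together with its adjacent transfers, the rest of the trip surviving.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CoverageError, SchemaError
from .survey_correction import TimetableSegment

CRUDE_GROUP = {
    "walk": None,  # walking never defines the class
    "bike_roller_skateboard": "other_active",
    "bus": "public_transport",
    "coach": "public_transport",
    "metro": "public_transport",
    "suburban_train": "public_transport",
    "tramway": "public_transport",
    "car_driver": "private_motorized",
    "car_passenger": "private_motorized",
    "long_distance_train": "other_long_distance",
    "plane": "other_long_distance",
    "jogging": "non_transport",
    "dog_walking": "non_transport",
    "ski_chairlift": "non_transport",
}

DETAILED_GROUP = {
    "walk": None,
    "bike_roller_skateboard": "other_active",
    "bus": "bus_coach",
    "coach": "bus_coach",
    "metro": "metro",
    "suburban_train": "suburban_train",
    "tramway": "tramway",
    "car_driver": "private_motorized_driver",
    "car_passenger": "private_motorized_passenger",
    "long_distance_train": "other_long_distance",
    "plane": "other_long_distance",
    "jogging": "non_transport",
    "dog_walking": "non_transport",
    "ski_chairlift": "non_transport",
}

CRUDE_CLASSES = ("entirely_walked", "other_active", "public_transport",
                 "private_motorized", "other_long_distance", "multi_mode")
DETAILED_CLASSES = ("entirely_walked", "other_active", "bus_coach", "metro",
                    "suburban_train", "tramway", "private_motorized_driver",
                    "private_motorized_passenger", "other_long_distance", "multi_mode")


@dataclass
class AnalyzedTrip:
    """A trip assembled from timetable segments, with classification flags."""

    trip_id: str
    participant_id: str
    day: int
    segments: list  # ordered TimetableSegments (stages and transfers)
    crude_class: str | None = None
    detailed_class: str | None = None
    excluded: bool = False
    reason: str | None = None
    accel_excluded: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def stages(self) -> list[TimetableSegment]:
        return [s for s in self.segments if s.kind == "trip_stage"]

    @property
    def start(self) -> float:
        return min(s.start for s in self.segments)

    @property
    def end(self) -> float:
        return max(s.end for s in self.segments)

    @property
    def distance_m(self) -> float:
        return sum(s.length_m for s in self.stages)

    @property
    def modes(self) -> list[str]:
        return [s.mode for s in self.stages]


def assemble_trips(timetable: list[TimetableSegment]) -> list[AnalyzedTrip]:
    """Group trip-related timetable segments (stages + transfers) by trip."""
    by_trip: dict = {}
    for seg in timetable:
        if seg.kind in ("trip_stage", "transfer") and seg.trip_id is not None:
            by_trip.setdefault((seg.participant_id, seg.trip_id), []).append(seg)
    trips = []
    for (pid, trip_id), segs in by_trip.items():
        segs.sort(key=lambda s: s.start)
        trips.append(AnalyzedTrip(trip_id, pid, segs[0].day, segs))
    trips.sort(key=lambda t: (t.participant_id, t.start))
    return trips


def classify_trip(trip: AnalyzedTrip, scheme: str = "crude") -> str:
    """Class label of one trip under the crude or detailed scheme."""
    if scheme not in ("crude", "detailed"):
        raise SchemaError(f"unknown scheme {scheme!r}")
    groups = CRUDE_GROUP if scheme == "crude" else DETAILED_GROUP
    if not trip.stages:
        raise SchemaError(f"trip {trip.trip_id} has no stages")
    seen = []
    for mode in trip.modes:
        if mode not in groups:
            raise SchemaError(f"unknown mode label {mode!r}")
        g = groups[mode]
        if g is not None and g not in seen:
            seen.append(g)
    if not seen:
        return "entirely_walked"
    if len(seen) == 1:
        return seen[0]
    return "multi_mode"


def classify_trips(trips: list[AnalyzedTrip]) -> list[AnalyzedTrip]:
    for trip in trips:
        trip.crude_class = classify_trip(trip, "crude")
        trip.detailed_class = classify_trip(trip, "detailed")
    return trips


def apply_exclusions(trips: list[AnalyzedTrip]) -> list[AnalyzedTrip]:
    """Apply the analytic-sample rules for non-trip movement.

    Ski/chairlift: the whole movement sequence is dropped.  Jogging or
    dog-walking: only the offending stages plus their adjacent transfers are
    cut; the trip survives (and is re-classified) if other stages remain.
    Long-distance train and plane stages are kept — they pertain to
    transport.  Retained segments are never altered.
    """
    out = []
    for trip in trips:
        modes = set(trip.modes)
        if "ski_chairlift" in modes:
            out.append(replace(trip, excluded=True, reason="ski_chairlift"))
            continue
        if modes & {"jogging", "dog_walking"}:
            keep, removed = [], 0
            segs = trip.segments
            drop = set()
            for i, seg in enumerate(segs):
                if seg.kind == "trip_stage" and seg.mode in ("jogging", "dog_walking"):
                    drop.add(i)
                    if i > 0 and segs[i - 1].kind == "transfer":
                        drop.add(i - 1)
                    if i + 1 < len(segs) and segs[i + 1].kind == "transfer":
                        drop.add(i + 1)
            keep = [s for i, s in enumerate(segs) if i not in drop]
            removed = len(segs) - len(keep)
            if any(s.kind == "trip_stage" for s in keep):
                kept_trip = replace(trip, segments=keep)
                kept_trip.crude_class = classify_trip(kept_trip, "crude")
                kept_trip.detailed_class = classify_trip(kept_trip, "detailed")
                kept_trip.meta = dict(trip.meta, removed_segments=removed)
                out.append(kept_trip)
            else:
                out.append(replace(trip, excluded=True, reason="jogging_dog_walking"))
            continue
        out.append(trip)
    return out


def flag_nonwear_trips(trips: list[AnalyzedTrip], wear_mask) -> list[AnalyzedTrip]:
    """Flag trips overlapping accelerometer nonwear, at the trip level.

    A trip is excluded from step analyses as soon as *any* epoch it overlaps
    is nonwear — even if the nonwear touches only a transfer.
    """
    flagged = []
    for trip in trips:
        start, end = trip.start, trip.end
        if not wear_mask.covers(start, end):
            raise CoverageError(
                f"trip {trip.trip_id} [{start}, {end}) outside the accelerometer epoch span")
        trip.accel_excluded = wear_mask.nonwear_overlap_s(start, end) > 0
        flagged.append(trip)
    return flagged


def trips_frame(trips: list[AnalyzedTrip]) -> pd.DataFrame:
    """Trip-level table (one row per trip) for export and metrics."""
    rows = []
    for t in trips:
        rows.append({
            "trip_id": t.trip_id, "participant": t.participant_id, "day": t.day,
            "start": t.start, "end": t.end,
            "crude_class": t.crude_class, "detailed_class": t.detailed_class,
            "excluded": t.excluded, "reason": t.reason,
            "accel_excluded": t.accel_excluded,
            "n_segments": len(t.segments),
            "distance_m": t.distance_m if not t.excluded else np.nan,
        })
    return pd.DataFrame(rows)
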