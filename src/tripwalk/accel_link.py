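"""Accelerometer processing: nonwear detection and step aggregation.

Nonwear is detected from sustained zero vector-magnitude counts with the
Choi-style rule (90-min zero window, <=2-min artefactual interruptions
flanked by >=30 min of zeros), evaluated on the package's epoch grid rather
than re-integrated 1-s counts — an approximation of the vendor
implementation, documented as such.  Steps are joined to timetable segments
by epoch midpoint, which conserves totals exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DAY_S
from .errors import CoverageError, GridError, UndefinedRateError
from .survey_correction import TimetableSegment


@dataclass
class WearMask:
    """Wear/nonwear partition of an epoch span."""

    epoch_s: float
    span: tuple  # (t0, t1) of the epoch grid
    nonwear: list = field(default_factory=list)  # disjoint (start, end) bouts

    @property
    def wear(self) -> list:
        """Wear intervals: the complement of the nonwear bouts in the span."""
        out = []
        cursor = self.span[0]
        for s, e in self.nonwear:
            if s > cursor:
                out.append((cursor, s))
            cursor = e
        if cursor < self.span[1]:
            out.append((cursor, self.span[1]))
        return out

    @property
    def wear_seconds(self) -> float:
        return sum(e - s for s, e in self.wear)

    def per_day(self) -> dict:
        """Wear intervals split at local-midnight day boundaries."""
        out: dict = {}
        for s, e in self.wear:
            d = int(s // DAY_S)
            while s < e:
                cut = min(e, (d + 1) * DAY_S)
                out.setdefault(d, []).append((s, cut))
                s, d = cut, d + 1
        return out

    def covers(self, start: float, end: float) -> bool:
        return self.span[0] <= start and end <= self.span[1]

    def nonwear_overlap_s(self, start: float, end: float) -> float:
        return sum(max(0.0, min(end, e) - max(start, s)) for s, e in self.nonwear)


def _check_grid(t: np.ndarray, epoch_s: float) -> None:
    if len(t) == 0:
        raise GridError("empty epoch stream")
    if len(t) > 1 and not np.allclose(np.diff(t), epoch_s):
        raise GridError("epoch grid has gaps or irregular spacing")


def detect_nonwear(epochs: pd.DataFrame, window_min: float = 90.0,
                   spike_tolerance_min: float = 2.0, flank_min: float = 30.0,
                   epoch_s: float | None = None) -> WearMask:
    """Choi-style nonwear bouts from vector-magnitude counts.

    A nonwear bout is a run of zero-vm epochs of at least ``window_min``
    minutes, allowed to contain nonzero interruptions of at most
    ``spike_tolerance_min`` minutes when the zero runs on both sides of the
    interruption last at least ``flank_min`` minutes.  The bout includes its
    interruptions.  Everything else is wear.
    """
    t = epochs["t"].to_numpy(float)
    if epoch_s is None:
        if len(t) < 2:
            raise GridError("cannot infer epoch length from fewer than 2 epochs")
        epoch_s = float(t[1] - t[0])
    _check_grid(t, epoch_s)
    vm = epochs["vm"].to_numpy(float)
    zero = vm == 0

    window_e = int(np.ceil(window_min * 60.0 / epoch_s))
    spike_e = int(spike_tolerance_min * 60.0 // epoch_s)
    flank_e = int(np.ceil(flank_min * 60.0 / epoch_s))

    # run-length encoding of the zero mask
    runs = []
    s = 0
    for k in range(1, len(zero) + 1):
        if k == len(zero) or zero[k] != zero[s]:
            runs.append((s, k - s, bool(zero[s])))
            s = k
    bouts = []
    i = 0
    while i < len(runs):
        start, length, is_zero = runs[i]
        if not is_zero:
            i += 1
            continue
        j = i
        while (j + 2 < len(runs)
               and runs[j + 1][1] <= spike_e
               and runs[j][1] >= flank_e
               and runs[j + 2][2] and runs[j + 2][1] >= flank_e):
            j += 2
        span_e = runs[j][0] + runs[j][1] - start
        if span_e >= window_e:
            bouts.append((t[start], t[start] + span_e * epoch_s))
        i = j + 1
    return WearMask(epoch_s, (t[0], t[-1] + epoch_s), bouts)


def steps_per_segment(epochs: pd.DataFrame, timetable: list[TimetableSegment],
                      epoch_s: float | None = None) -> np.ndarray:
    """Assign each epoch's steps to the timetable segment containing its
    midpoint; returns the per-segment totals (and sets ``segment.steps``).

    Midpoint assignment is deterministic and conserves daily totals exactly:
    every epoch whose midpoint falls inside the surveyed span lands in
    exactly one segment, because the timetable tiles each surveyed day.
    """
    t = epochs["t"].to_numpy(float)
    if epoch_s is None:
        if len(t) < 2:
            raise GridError("cannot infer epoch length from fewer than 2 epochs")
        epoch_s = float(t[1] - t[0])
    _check_grid(t, epoch_s)
    if not timetable:
        return np.zeros(0)
    t0, t1 = t[0], t[-1] + epoch_s
    for seg in timetable:
        if seg.start < t0 - 1e-9 or seg.end > t1 + 1e-9:
            raise CoverageError(
                f"segment [{seg.start}, {seg.end}) outside epoch coverage [{t0}, {t1})")
    order = np.argsort([seg.start for seg in timetable], kind="stable")
    segs = [timetable[i] for i in order]
    starts = np.array([s.start for s in segs])
    ends = np.array([s.end for s in segs])
    mids = t + epoch_s / 2.0
    steps = epochs["steps"].to_numpy(float)
    idx = np.searchsorted(starts, mids, side="right") - 1
    totals = np.zeros(len(segs))
    valid = (idx >= 0) & (mids < ends[np.clip(idx, 0, len(segs) - 1)])
    np.add.at(totals, idx[valid], steps[valid])
    out = np.zeros(len(timetable))
    for k, i in enumerate(order):
        timetable[i].steps = float(totals[k])
        out[i] = totals[k]
    return out


def steps_per_8h_wear(trip_steps: float, wear) -> float:
    """Steps normalized per 8-hour unit of accelerometer wear time.

    The surveyed-day count cannot serve as the denominator because days
    contain nonwear; wear time in units of 8 h is used instead.
    """
    wear_seconds = wear.wear_seconds if isinstance(wear, WearMask) else float(wear)
    if wear_seconds <= 0:
        raise UndefinedRateError("zero accelerometer wear time")
    return float(trip_steps) / (wear_seconds / 28_800.0)
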