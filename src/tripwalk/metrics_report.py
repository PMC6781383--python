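"""Headline walking metrics from the validated timetable.

Distance walked in a trip is the summed polyline length of its walking
stages (transfer episodes are point locations and contribute no distance);
steps are accumulated over the entire trip, transfers included.  Attribution
shares answer the study's central question: what fraction of all transport
walking (distance, steps) is generated by each kind of trip — in particular
by public transport.

Quantile conventions: the weighted quantile is inverse-CDF (smallest value
whose cumulative normalized weight reaches the probability), and the
unweighted summaries use the same definition with unit weights, so the two
agree by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedRateError
from .trip_classification import AnalyzedTrip

log = logging.getLogger(__name__)

PT_DETAILED = ("bus_coach", "metro", "suburban_train", "tramway")


@dataclass
class QuantileSummary:
    """Median with the interdecile range (10th and 90th percentiles)."""

    median: float
    p10: float
    p90: float

    def as_tuple(self):
        return (self.median, self.p10, self.p90)


def weighted_quantiles(values, weights, probs) -> np.ndarray:
    """Inverse-CDF quantiles of a weighted sample.

    Quantile ``q`` is the smallest value whose cumulative normalized weight
    is at least ``q``.  With unit weights this reduces to the ordinary
    (type-1) empirical quantile.
    """
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    probs = np.atleast_1d(np.asarray(probs, float))
    if np.any(weights < 0):
        raise ValueError("weights must be >= 0")
    total = weights.sum()
    if total <= 0:
        raise ValueError("sum of weights must be > 0")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probs must lie in [0, 1]")
    order = np.argsort(values, kind="stable")
    v = values[order]
    cw = np.cumsum(weights[order]) / total
    idx = np.searchsorted(cw, probs, side="left")
    return v[np.clip(idx, 0, len(v) - 1)]


def quantile_summary(values, weights=None) -> QuantileSummary:
    values = np.asarray(values, float)
    if weights is None:
        weights = np.ones_like(values)
    m, p10, p90 = weighted_quantiles(values, weights, [0.5, 0.1, 0.9])
    return QuantileSummary(float(m), float(p10), float(p90))


# ------------------------------------------------------------ trip metrics

def distance_walked_per_trip(trip: AnalyzedTrip) -> float:
    """Meters walked in one trip: summed length of its walking stages.

    Transfers contribute nothing — they are represented as point locations
    with no mapped distance.
    """
    return sum(s.length_m for s in trip.stages if s.mode == "walk")


def duration_walked_per_trip(trip: AnalyzedTrip) -> float:
    return sum(s.duration_s for s in trip.stages if s.mode == "walk")


def trip_steps(trip: AnalyzedTrip) -> float:
    """Steps over the entire trip, non-walking stages and transfers included."""
    return float(np.nansum([s.steps for s in trip.segments]))


def build_metrics_table(trips: list[AnalyzedTrip], zones: dict | None = None) -> pd.DataFrame:
    """One row per retained trip: distances, steps, classes, urbanicity zone."""
    rows = []
    for t in trips:
        if t.excluded:
            continue
        rows.append({
            "participant": t.participant_id, "day": t.day, "trip_id": t.trip_id,
            "crude_class": t.crude_class, "detailed_class": t.detailed_class,
            "distance_total_km": t.distance_m / 1000.0,
            "distance_walked_km": distance_walked_per_trip(t) / 1000.0,
            "duration_walked_s": duration_walked_per_trip(t),
            "steps_trip": trip_steps(t),
            "accel_excluded": t.accel_excluded,
            "zone": (zones or {}).get(t.participant_id),
        })
    return pd.DataFrame(rows)


def attribution_shares(table: pd.DataFrame, metric: str = "distance_walked",
                       scheme: str = "crude") -> pd.Series:
    """Percentage of the overall metric accumulated in each trip class."""
    col = {"distance_walked": "distance_walked_km", "steps": "steps_trip"}[metric]
    df = table
    if metric == "steps":
        df = table[~table["accel_excluded"]]
    if len(df) == 0:
        raise UndefinedRateError("empty metrics table")
    totals = df.groupby(f"{scheme}_class")[col].sum()
    grand = totals.sum()
    if grand <= 0:
        raise UndefinedRateError(f"zero total {metric}")
    return (100.0 * totals / grand).rename(f"pct_{metric}")


def per_day_cumulations(table: pd.DataFrame, col: str, scheme: str = "crude") -> pd.DataFrame:
    """Per participant-day totals of ``col`` by class, zero-filled.

    Zero-filling matters: the distribution of per-day cumulated distance in
    a class is taken over *all* participant-days, including those of people
    who never use the class.
    """
    pv = table.pivot_table(index=["participant", "day"], columns=f"{scheme}_class",
                           values=col, aggfunc="sum", fill_value=0.0)
    all_days = table[["participant", "day"]].drop_duplicates()
    pv = pv.reindex(pd.MultiIndex.from_frame(all_days), fill_value=0.0)
    return pv


def walking_intensity(trips: list[AnalyzedTrip]) -> pd.DataFrame:
    """Walking-intensity summaries for walked trips and PT access walking.

    Speed of walking (km/h) is summarized with stages weighted by the
    distance walked; cadence (steps/min) with stages weighted by the
    duration walked.  Rows: entirely walked trips, then the walking stages
    of public-transport trips overall and by PT sub-mode.
    """
    groups: dict[str, list] = {"entirely_walked": [], "public_transport_all": []}
    for m in PT_DETAILED:
        groups[f"pt_{m}"] = []
    for t in trips:
        if t.excluded:
            continue
        is_pt = t.crude_class == "public_transport"
        for s in t.stages:
            if s.mode != "walk":
                continue
            if s.duration_s <= 0:
                log.warning("zero-duration walking stage skipped: %s", t.trip_id)
                continue
            rec = (s.length_m, s.duration_s, s.steps)
            if t.crude_class == "entirely_walked":
                groups["entirely_walked"].append(rec)
            elif is_pt:
                groups["public_transport_all"].append(rec)
                key = f"pt_{t.detailed_class}"
                if key in groups:
                    groups[key].append(rec)
    rows = {}
    for name, recs in groups.items():
        if not recs:
            continue
        length = np.array([r[0] for r in recs])
        dur = np.array([r[1] for r in recs])
        steps = np.array([r[2] for r in recs])
        speed = 3.6 * length / dur
        cadence = steps / (dur / 60.0)
        sp = quantile_summary(speed, weights=length)
        ok = ~np.isnan(cadence)
        cad = quantile_summary(cadence[ok], weights=dur[ok]) if ok.any() else None
        rows[name] = {
            "n_stages": len(recs),
            "speed_median": sp.median, "speed_p10": sp.p10, "speed_p90": sp.p90,
            "cadence_median": cad.median if cad else np.nan,
            "cadence_p10": cad.p10 if cad else np.nan,
            "cadence_p90": cad.p90 if cad else np.nan,
        }
    return pd.DataFrame(rows).T


def transfer_cadence(trips: list[AnalyzedTrip]) -> QuantileSummary | None:
    """Steps/min during punctual transfer episodes of PT trips.

    Reported separately and flagged low-confidence: transfer timestamps are
    the least accurate part of the timetable, so these cadences mix true
    waiting with timestamping error.
    """
    recs = []
    for t in trips:
        if t.excluded or t.crude_class != "public_transport":
            continue
        for s in t.segments:
            if s.kind == "transfer" and s.duration_s > 0 and not np.isnan(s.steps):
                recs.append((s.steps / (s.duration_s / 60.0), s.duration_s))
    if not recs:
        return None
    return quantile_summary([r[0] for r in recs], weights=[r[1] for r in recs])


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df).

    Returns (H, p).  If every value is identical the statistic is 0 and the
    p-value 1.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    offsets = np.cumsum([0] + [len(g) for g in groups])
    h = 0.0
    for k, g in enumerate(groups):
        r = ranks[offsets[k]:offsets[k + 1]]
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    if tie_corr == 0.0:  # all values identical
        return 0.0, 1.0
    h /= tie_corr
    p = float(stats.chi2.sf(h, len(groups) - 1))
    return float(h), p


def urbanicity_strata(table: pd.DataFrame) -> dict:
    """Re-derive the headline metrics within each urbanicity zone.

    Returns per-zone median distance walked per participant-day, per-zone
    attribution shares, and a monotonic-contrast check of the
    public-transport share across core city -> close suburb -> far suburb.
    """
    from .config import ZONES

    out: dict = {"zones": {}, "pt_share_walked": {}, "monotone_pt_decline": None}
    for zone in ZONES:
        sub = table[table["zone"] == zone]
        if len(sub) == 0:
            log.warning("urbanicity stratum %s is empty; omitted", zone)
            continue
        daily = sub.groupby(["participant", "day"])["distance_walked_km"].sum()
        shares = attribution_shares(sub, "distance_walked", "crude")
        out["zones"][zone] = {
            "median_distance_walked_km_per_day": float(daily.median()),
            "shares_pct": shares.to_dict(),
        }
        out["pt_share_walked"][zone] = float(shares.get("public_transport", 0.0))
    present = [z for z in ZONES if z in out["pt_share_walked"]]
    if len(present) == len(ZONES):
        vals = [out["pt_share_walked"][z] for z in ZONES]
        out["monotone_pt_decline"] = bool(vals[0] >= vals[1] >= vals[2])
    return out
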