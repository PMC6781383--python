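"""Travel-mode assignment for candidate trip stages.

Each stage is scored per mode from three evidence sources — its smoothed
speed versus per-mode speed bands, the presence of transit stations of that
mode near both endpoints (boosted when the two stations share a line), and
the participant's habitual-mode weights from the baseline survey:

    score(mode) = w_speed * band_match + w_station * station_evidence
                  + w_prior * prior(mode)

Driver versus passenger is not inferable from sensors, so the algorithm
emits a generic ``car``; the split is resolved later by the survey.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ALGO_MODES, DIARY_TO_ALGO, PipelineConfig, TRANSIT_MODES
from .errors import CoverageError, InvalidStageError
from .geo import polyline_length_m
from .gps_pipeline import CandidateSegment
from .network import TransitNetwork
from .synthetic_world import GroundTruthDiary


@dataclass
class ModePrior:
    """Habitual-use weights over the algorithm mode alphabet (sums to 1)."""

    participant_id: str
    weights: dict

    def __post_init__(self):
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("prior weights must be >= 0")
        total = sum(self.weights.values())
        if total > 0:
            self.weights = {m: w / total for m, w in self.weights.items()}

    @classmethod
    def uniform(cls, participant_id: str = "") -> "ModePrior":
        return cls(participant_id, {m: 1.0 for m in ALGO_MODES})

    def __call__(self, mode: str) -> float:
        return self.weights.get(mode, 0.0)


@dataclass
class ModeScore:
    """Per-mode scores for one stage, with the argmax label and evidence flags."""

    stage: CandidateSegment
    scores: dict
    label: str
    evidence: dict = field(default_factory=dict)

    @property
    def start(self) -> float:
        return self.stage.start

    @property
    def end(self) -> float:
        return self.stage.end


@dataclass
class ImputedTransfer:
    """Zero-length placeholder between two differently-labelled stages."""

    t: float
    location: np.ndarray


def _stage_speed_kmh(stage: CandidateSegment) -> float:
    if "median_speed_kmh" in stage.meta:
        return float(stage.meta["median_speed_kmh"])
    pts = stage.points
    d = polyline_length_m(pts[:, 1:3])
    dur = max(stage.end - stage.start, 1e-9)
    return 3.6 * d / dur


def score_stage(stage: CandidateSegment, prior: ModePrior, network: TransitNetwork,
                config: PipelineConfig | None = None) -> ModeScore:
    """Score one move stage against every algorithm mode."""
    cfg = config or PipelineConfig()
    if stage.points is None or len(stage.points) == 0:
        raise InvalidStageError("stage has an empty polyline")
    v = _stage_speed_kmh(stage)
    length_km = polyline_length_m(stage.points[:, 1:3]) / 1000.0
    p0, p1 = stage.points[0, 1:3], stage.points[-1, 1:3]

    near0 = network.stations_near(p0, cfg.station_snap_m) if network is not None else []
    near1 = network.stations_near(p1, cfg.station_snap_m) if network is not None else []
    lines0 = {(ln.line_id, ln.mode) for ln, _, _ in near0}
    lines1 = {(ln.line_id, ln.mode) for ln, _, _ in near1}
    modes0 = {m for _, m in lines0}
    modes1 = {m for _, m in lines1}
    shared_lines = {lid for lid, _ in lines0} & {lid for lid, _ in lines1}

    scores = {}
    evidence = {"speed_band": [], "station_start": sorted(modes0),
                "station_end": sorted(modes1), "same_line": bool(shared_lines)}
    for mode in ALGO_MODES:
        lo, hi = cfg.speed_bands[mode]
        band = 1.0 if lo <= v < hi else 0.0
        if mode == "long_distance" and length_km < cfg.long_distance_min_km:
            band = 0.0
        if band:
            evidence["speed_band"].append(mode)
        station = 0.0
        if mode in TRANSIT_MODES and mode in modes0 and mode in modes1:
            same = any(m == mode for lid, m in lines0 if lid in shared_lines)
            station = 1.0 if same else 0.7
        scores[mode] = cfg.w_speed * band + cfg.w_station * station + cfg.w_prior * prior(mode)
    best = max(ALGO_MODES, key=lambda m: (scores[m], -ALGO_MODES.index(m)))
    return ModeScore(stage, scores, best, evidence)


def impute_modes(stages: list[CandidateSegment], prior: ModePrior,
                 network: TransitNetwork, config: PipelineConfig | None = None) -> list:
    """Label every stage; insert a zero-length transfer placeholder at the
    shared endpoint of consecutive, differently-labelled, contiguous stages."""
    out: list = []
    prev: ModeScore | None = None
    for stage in stages:
        ms = score_stage(stage, prior, network, config)
        if (prev is not None and prev.label != ms.label
                and abs(prev.end - ms.start) < 1e-9):
            out.append(ImputedTransfer(ms.start, stage.points[0, 1:3].copy()))
        out.append(ms)
        prev = ms
    return out


# ------------------------------------------------------- agreement reporting

@dataclass
class ModeAgreementReport:
    """Time-weighted agreement between imputed and true mode timelines.

    Transfer episodes are excluded from every denominator (their punctual
    timestamps are the least reliable part of the timeline); the flag
    records this choice.
    """

    truth_transport_s: float
    imputed_transport_s: float
    joint_transport_s: float
    transport_detected_frac: float      # (a) truth transport labelled transport
    transport_confirmed_frac: float     # (b) imputed transport that is true transport
    mode_accuracy: float                # (c) matching-mode share of joint time
    per_mode: pd.DataFrame              # truth_s, correct_s, fraction per mode
    transfers_excluded: bool = True

    def to_dict(self) -> dict:
        return {
            "truth_transport_s": self.truth_transport_s,
            "imputed_transport_s": self.imputed_transport_s,
            "joint_transport_s": self.joint_transport_s,
            "transport_detected_frac": self.transport_detected_frac,
            "transport_confirmed_frac": self.transport_confirmed_frac,
            "mode_accuracy": self.mode_accuracy,
            "transfers_excluded": self.transfers_excluded,
            "per_mode": self.per_mode.to_dict(orient="index"),
        }


def _truth_timeline(truth: GroundTruthDiary):
    """(start, end, label) records: algo mode, 'visit', 'transfer', or None."""
    recs = []
    for _, kind, mode, s0, s1, _, _ in truth.iter_segments():
        if kind == "visit":
            label = "visit"
        elif kind == "transfer":
            label = "transfer"
        else:
            label = DIARY_TO_ALGO.get(mode)  # None => out of scope (jogging etc.)
        recs.append((s0, s1, label))
    recs.sort()
    return recs


def mode_accuracy_report(imputed: list, truth: GroundTruthDiary) -> ModeAgreementReport:
    """Compare an imputed stage timeline with the ground-truth diary.

    Durations are computed by exact interval intersection over the truth
    diary's day span.  Anything outside an imputed stage counts as
    non-transport on the imputed side.
    """
    stages = [m for m in imputed if isinstance(m, ModeScore)]
    truth_recs = _truth_timeline(truth)
    if not truth_recs:
        raise CoverageError("truth diary is empty")
    t_lo, t_hi = truth_recs[0][0], truth_recs[-1][1]
    if stages:
        i_lo = min(s.start for s in stages)
        i_hi = max(s.end for s in stages)
        if i_hi <= t_lo or i_lo >= t_hi:
            raise CoverageError("imputed and truth timelines do not overlap in time")

    breaks = sorted({t_lo, t_hi}
                    | {r[0] for r in truth_recs} | {r[1] for r in truth_recs}
                    | {s.start for s in stages} | {s.end for s in stages})
    breaks = [b for b in breaks if t_lo <= b <= t_hi]

    truth_starts = np.array([r[0] for r in truth_recs])
    stage_starts = np.array([s.start for s in stages]) if stages else np.zeros(0)

    acc: dict = {}
    for a, b in zip(breaks[:-1], breaks[1:]):
        if b <= a:
            continue
        mid = (a + b) / 2.0
        ti = int(np.searchsorted(truth_starts, mid, side="right") - 1)
        t_label = truth_recs[ti][2] if 0 <= ti < len(truth_recs) and mid < truth_recs[ti][1] else None
        i_label = "visit"
        if len(stage_starts):
            si = int(np.searchsorted(stage_starts, mid, side="right") - 1)
            if 0 <= si < len(stages) and mid < stages[si].end:
                i_label = stages[si].label
        acc[(t_label, i_label)] = acc.get((t_label, i_label), 0.0) + (b - a)

    modes = set(ALGO_MODES)
    truth_transport = sum(d for (tl, _il), d in acc.items() if tl in modes)
    # imputed transport counted only where the truth label is defined and is
    # not a transfer, so both reciprocal fractions share one denominator rule
    imp_transport = sum(d for (tl, il), d in acc.items()
                        if il in modes and tl not in ("transfer", None))
    joint = sum(d for (tl, il), d in acc.items() if tl in modes and il in modes)
    correct = {m: acc.get((m, m), 0.0) for m in ALGO_MODES}
    truth_joint = {m: sum(d for (tl, il), d in acc.items() if tl == m and il in modes)
                   for m in ALGO_MODES}
    per_mode = pd.DataFrame({"truth_s": truth_joint, "correct_s": correct})
    per_mode["fraction"] = per_mode["correct_s"] / per_mode["truth_s"].where(per_mode["truth_s"] > 0)

    both = sum(correct.values())
    return ModeAgreementReport(
        truth_transport_s=truth_transport,
        imputed_transport_s=imp_transport,
        joint_transport_s=joint,
        transport_detected_frac=joint / truth_transport if truth_transport > 0 else np.nan,
        transport_confirmed_frac=joint / imp_transport if imp_transport > 0 else np.nan,
        mode_accuracy=both / joint if joint > 0 else np.nan,
        per_mode=per_mode,
    )
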