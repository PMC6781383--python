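"""End-to-end orchestration: world -> sensors -> algorithm -> survey -> metrics.

`run_study` is the one-call entry point used by the CLI, the test-suite's
integration fixtures and the acceptance script: it renders each
participant's sensor streams, runs the algorithm-only GPS chain, emulates
the prompted-recall survey, joins accelerometer steps, and assembles the
study-level tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accel_link import WearMask, detect_nonwear, steps_per_8h_wear, steps_per_segment
from .config import PipelineConfig, WorldParams
from .gps_pipeline import (CandidateSegment, detect_visits, filter_low_speed,
                           raw_daily_distance, split_stages)
from .metrics_report import build_metrics_table
from .mode_imputation import (ModeAgreementReport, ModePrior, ModeScore,
                              impute_modes, mode_accuracy_report)
from .network import StreetGrid, TransitNetwork
from .survey_correction import (RecallModel, ThreeWayDistanceReport, TimetableSegment,
                                algorithm_daily_distance, reconcile,
                                survey_daily_distance, three_way_distance_report)
from .synthetic_world import GroundTruthDiary, _pid_key, generate_world, render_accel, render_gps
from .trip_classification import (AnalyzedTrip, apply_exclusions, assemble_trips,
                                  classify_trips, flag_nonwear_trips)


@dataclass
class ParticipantResult:
    diary: GroundTruthDiary
    gps: pd.DataFrame
    accel: pd.DataFrame
    filtered: pd.DataFrame
    segments: list[CandidateSegment]
    imputed: list
    timetable: list[TimetableSegment]
    wear: WearMask
    trips: list[AnalyzedTrip]
    accuracy: ModeAgreementReport | None


@dataclass
class StudyResult:
    network: TransitNetwork
    grid: StreetGrid
    participants: list[ParticipantResult]
    metrics: pd.DataFrame
    zones: dict
    distances: ThreeWayDistanceReport
    accuracy: ModeAgreementReport | None

    @property
    def trips(self) -> list[AnalyzedTrip]:
        return [t for p in self.participants for t in p.trips]

    def steps_per_8h_by_participant(self) -> pd.Series:
        """Trip steps per 8 h of wear time, per participant (step sample)."""
        rows = {}
        for p in self.participants:
            total = sum(
                np.nansum([s.steps for s in t.segments])
                for t in p.trips if not t.excluded and not t.accel_excluded)
            rows[p.diary.participant_id] = steps_per_8h_wear(total, p.wear)
        return pd.Series(rows)


def process_participant(diary: GroundTruthDiary, network: TransitNetwork,
                        grid: StreetGrid, world: WorldParams,
                        pipe: PipelineConfig) -> ParticipantResult:
    sensor = world.sensor
    gps = render_gps(diary, sensor)
    accel = render_accel(diary, sensor)

    filtered = filter_low_speed(gps, pipe.speed_threshold_kmh)
    segments = detect_visits(filtered, pipe.dwell_min_s, pipe.visit_radius_m,
                             diary.participant_id)
    stages = []
    for seg in segments:
        if seg.kind == "move":
            stages.extend(split_stages(seg, network, pipe))
    prior = ModePrior(diary.participant_id, dict(diary.prior))
    imputed = impute_modes(stages, prior, network, pipe)
    try:
        accuracy = mode_accuracy_report(imputed, diary)
    except Exception:
        accuracy = None

    recall = RecallModel(pipe.recall_prob, pipe.recall_noise_sd_s)
    rng = np.random.default_rng([sensor.seed, _pid_key(diary.participant_id), 13])
    timetable = reconcile(segments, diary, recall, grid, pipe, rng)

    wear = detect_nonwear(accel, epoch_s=sensor.accel_epoch_s)
    steps_per_segment(accel, timetable, epoch_s=sensor.accel_epoch_s)

    trips = assemble_trips(timetable)
    trips = classify_trips(trips)
    trips = apply_exclusions(trips)
    trips = flag_nonwear_trips(trips, wear)
    return ParticipantResult(diary, gps, accel, filtered, segments, imputed,
                             timetable, wear, trips, accuracy)


def pool_accuracy(reports: list[ModeAgreementReport]) -> ModeAgreementReport | None:
    """Combine per-participant agreement reports by summing durations."""
    reports = [r for r in reports if r is not None]
    if not reports:
        return None
    truth = sum(r.truth_transport_s for r in reports)
    imp = sum(r.imputed_transport_s for r in reports)
    joint = sum(r.joint_transport_s for r in reports)
    per_mode = sum(r.per_mode[["truth_s", "correct_s"]] for r in reports)
    per_mode["fraction"] = per_mode["correct_s"] / per_mode["truth_s"].where(per_mode["truth_s"] > 0)
    correct = float(per_mode["correct_s"].sum())
    return ModeAgreementReport(
        truth_transport_s=truth, imputed_transport_s=imp, joint_transport_s=joint,
        transport_detected_frac=joint / truth if truth > 0 else np.nan,
        transport_confirmed_frac=joint / imp if imp > 0 else np.nan,
        mode_accuracy=correct / joint if joint > 0 else np.nan,
        per_mode=per_mode,
    )


def _per_day_frame(series_by_pid: dict) -> pd.DataFrame:
    frames = []
    for pid, s in series_by_pid.items():
        df = s.to_frame()
        df.index = pd.MultiIndex.from_product([[pid], df.index], names=["participant", "day"])
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["distance_m"])
    return pd.concat(frames)


def run_study(world: WorldParams, pipe: PipelineConfig, n_participants: int,
              n_days: int, seed: int | None = None) -> StudyResult:
    """Run the full measurement chain on a freshly generated world."""
    if seed is not None:
        world.sensor.seed = int(seed)
    world.validate()
    pipe.validate()
    network, diaries = generate_world(world, n_participants, n_days)
    grid = StreetGrid(world)

    participants = [process_participant(d, network, grid, world, pipe) for d in diaries]

    raw = _per_day_frame({p.diary.participant_id: raw_daily_distance(p.filtered)
                          for p in participants})
    algo = _per_day_frame({p.diary.participant_id: algorithm_daily_distance(p.segments)
                           for p in participants})
    survey = _per_day_frame({p.diary.participant_id: survey_daily_distance(p.timetable)
                             for p in participants})
    distances = three_way_distance_report(raw, algo, survey)

    zones = {p.diary.participant_id: p.diary.zone for p in participants}
    trips = [t for p in participants for t in p.trips]
    metrics = build_metrics_table(trips, zones)
    accuracy = pool_accuracy([p.accuracy for p in participants])
    return StudyResult(network, grid, participants, metrics, zones, distances, accuracy)
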