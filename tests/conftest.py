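"""Shared fixtures: small synthetic studies and geometry helpers.

Study fixtures are session-scoped because a full pipeline run is the
expensive part of the suite; each is a distinct stated world (noise-free,
default artefacts, artefacts-without-dropout) reused by many tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from tripwalk.config import PipelineConfig, WorldParams
from tripwalk.geo import LocalProjection
from tripwalk.pipeline import run_study
from tripwalk.survey_correction import TimetableSegment

LON0, LAT0 = 2.35, 48.85
PROJ = LocalProjection(LON0, LAT0)


def straight_polyline(length_m: float, n: int = 2, origin_xy=(0.0, 0.0)) -> np.ndarray:
    """Eastward straight lon/lat polyline of a given haversine length."""
    x = np.linspace(0.0, length_m, n) + origin_xy[0]
    y = np.full(n, origin_xy[1])
    return PROJ.to_lonlat(np.column_stack([x, y]))


def make_stage(mode: str, start: float, end: float, length_m: float,
               pid: str = "P", day: int = 0, trip_id: str = "T1",
               steps: float = np.nan, origin_xy=(0.0, 0.0)) -> TimetableSegment:
    return TimetableSegment(pid, day, "trip_stage", start, end, mode=mode,
                            polyline=straight_polyline(length_m, origin_xy=origin_xy),
                            trip_id=trip_id, steps=steps)


def make_transfer(start: float, end: float, pid: str = "P", day: int = 0,
                  trip_id: str = "T1", steps: float = np.nan) -> TimetableSegment:
    return TimetableSegment(pid, day, "transfer", start, end, trip_id=trip_id,
                            location=np.array([LON0, LAT0]), steps=steps)


@pytest.fixture(scope="session")
def noise_free_study():
    """Artefact-free world: jitter, bursts, dropouts and tunnels all off."""
    world = WorldParams()
    world.sensor = world.sensor.noise_free()
    return run_study(world, PipelineConfig(), 5, 3, seed=11)


@pytest.fixture(scope="session")
def noisy_study():
    """Default artefact configuration (the stated noisy world)."""
    return run_study(WorldParams(), PipelineConfig(), 8, 4, seed=7)


@pytest.fixture(scope="session")
def artefact_no_dropout_study():
    """Artefacts on, but no dropouts and no tunnels: every trip observed."""
    world = WorldParams()
    world.sensor.dropout_prob = 0.0
    world.sensor.underground_visible_prob = 1.0
    return run_study(world, PipelineConfig(), 6, 3, seed=13)
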