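"""Mode vocabularies and configuration objects.

Two mode alphabets coexist:

* **diary modes** — the labels a participant can report in the mobility
  survey (walking, bike/roller/skateboard, four public-transport modes,
  car as driver or passenger, long-distance modes, and non-transport
  movement such as jogging or skiing);
* **algorithm modes** — the coarser labels the sensor-only pipeline can
  plausibly distinguish (driver vs. passenger, for instance, is not
  inferable from GPS and is only resolved by the survey).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .errors import ConfigurationError

# ------------------------------------------------------------------ modes

DIARY_MODES = (
    "walk",
    "bike_roller_skateboard",
    "bus",
    "coach",
    "metro",
    "suburban_train",
    "tramway",
    "car_driver",
    "car_passenger",
    "long_distance_train",
    "plane",
    "jogging",
    "dog_walking",
    "ski_chairlift",
)

TRANSIT_MODES = ("bus", "metro", "suburban_train", "tramway")

#: modes whose presence triggers analytic exclusion rules
NON_TRANSPORT_MODES = ("jogging", "dog_walking", "ski_chairlift")

#: fixed order used for deterministic tie-breaks in mode scoring
ALGO_MODES = ("walk", "bike", "bus", "metro", "suburban_train", "tramway", "car", "long_distance")

#: diary mode -> algorithm-alphabet mode (None = outside the algorithm's scope)
DIARY_TO_ALGO = {
    "walk": "walk",
    "bike_roller_skateboard": "bike",
    "bus": "bus",
    "coach": "bus",
    "metro": "metro",
    "suburban_train": "suburban_train",
    "tramway": "tramway",
    "car_driver": "car",
    "car_passenger": "car",
    "long_distance_train": "long_distance",
    "plane": "long_distance",
    "jogging": None,
    "dog_walking": None,
    "ski_chairlift": None,
}

ZONES = ("core_city", "close_suburb", "far_suburb")

# typical in-motion speeds (km/h) used by the synthetic diary generator
DEFAULT_SPEEDS_KMH = {
    "walk": 4.8,
    "walk_pt_access": 5.2,  # access/egress walks are brisker (schedule pressure)
    "bike_roller_skateboard": 14.0,
    "bus": 18.0,
    "coach": 55.0,
    "metro": 28.0,
    "suburban_train": 55.0,
    "tramway": 19.0,
    "car_driver": 30.0,
    "car_passenger": 30.0,
    "long_distance_train": 160.0,
    "plane": 700.0,
    "jogging": 8.5,
    "dog_walking": 3.5,
    "ski_chairlift": 15.0,
}

# step cadence (steps/min): mean, sd — drawn per accelerometer epoch
DEFAULT_CADENCE = {
    "walk": (84.0, 12.0),
    "walk_pt_access": (87.0, 12.0),
    "bike_roller_skateboard": (8.0, 4.0),
    "vehicle": (1.0, 1.0),
    "jogging": (150.0, 15.0),
    "dog_walking": (60.0, 15.0),
    "transfer": (30.0, 12.0),
    "visit": (6.0, 5.0),
}

#: trip-mode mixture by residence zone; chosen once to mirror a dense-core
#: region: walking and public transport dominate the core, the car the far
#: suburbs.  Metro/tramway do not serve the far suburb.
DEFAULT_MODE_MIX = {
    "core_city": {
        "walk": 0.50, "bike_roller_skateboard": 0.05, "bus": 0.03, "metro": 0.13,
        "suburban_train": 0.015, "tramway": 0.01, "car_driver": 0.195,
        "car_passenger": 0.045, "jogging": 0.015, "dog_walking": 0.01,
    },
    "close_suburb": {
        "walk": 0.43, "bike_roller_skateboard": 0.05, "bus": 0.03, "metro": 0.05,
        "suburban_train": 0.025, "tramway": 0.015, "car_driver": 0.33,
        "car_passenger": 0.05, "jogging": 0.015, "dog_walking": 0.005,
    },
    "far_suburb": {
        "walk": 0.32, "bike_roller_skateboard": 0.04, "bus": 0.02, "metro": 0.0,
        "suburban_train": 0.04, "tramway": 0.0, "car_driver": 0.50,
        "car_passenger": 0.055, "jogging": 0.015, "dog_walking": 0.01,
    },
}

#: share of residences per zone (core / close / far)
DEFAULT_ZONE_SHARES = {"core_city": 0.35, "close_suburb": 0.45, "far_suburb": 0.20}

DAY_S = 86_400.0


# ----------------------------------------------------------- configuration

@dataclass
class SensorConfig:
    """Parameters of the two simulated sensors and their artefact models.

    The GPS period (5 s) matches field practice with logging receivers;
    artefact magnitudes (jitter, pseudo-ambulation bursts, dropouts) are
    conventions, not estimates, and are all switchable off.
    """

    gps_period_s: float = 5.0
    #: sparser logging cadence while stationary at a place
    visit_period_s: float = 30.0
    accel_epoch_s: float = 60.0
    #: stationary GPS scatter at fixed places (AR(1) stationary sd, meters)
    jitter_visit_sd_m: float = 15.0
    #: white position noise added to in-trip fixes (meters)
    jitter_trip_sd_m: float = 5.0
    #: probability that a whole trip leaves no GPS trace (receiver left home)
    dropout_prob: float = 0.05
    #: probability that a visit contains one pseudo-ambulation burst
    pseudo_ambulation_rate: float = 0.5
    #: mean-reversion scale of a burst (stationary sd, m) and per-fix kick (m)
    burst_sd_m: float = 80.0
    burst_step_sd_m: float = 12.0
    #: daily accelerometer wear window (seconds from local midnight)
    wear_start_s: float = 6.5 * 3600
    wear_end_s: float = 22.5 * 3600
    #: dwell at intermediate transit stations folded into rides (seconds)
    station_dwell_s: float = 20.0
    #: probability that a metro ride is above ground and visible to GPS
    underground_visible_prob: float = 0.3
    cadence: dict = field(default_factory=lambda: dict(DEFAULT_CADENCE))
    seed: int = 0

    def validate(self) -> "SensorConfig":
        for name in ("gps_period_s", "visit_period_s", "accel_epoch_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("dropout_prob", "pseudo_ambulation_rate", "underground_visible_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("jitter_visit_sd_m", "jitter_trip_sd_m", "burst_sd_m", "burst_step_sd_m"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.wear_start_s < self.wear_end_s <= DAY_S:
            raise ConfigurationError("wear_start_s/wear_end_s must satisfy 0 <= start < end <= 86400")
        for key, (mean, sd) in self.cadence.items():
            if mean < 0 or sd < 0:
                raise ConfigurationError(f"cadence[{key}] mean and sd must be >= 0")
        return self

    def noise_free(self) -> "SensorConfig":
        """Copy with every artefact channel switched off (used in tests)."""
        return replace(
            self,
            jitter_visit_sd_m=0.0,
            jitter_trip_sd_m=0.0,
            dropout_prob=0.0,
            pseudo_ambulation_rate=0.0,
            underground_visible_prob=1.0,
        )


@dataclass
class WorldParams:
    """Geometry and behaviour of the synthetic region and its residents."""

    #: region center (Paris-like) and half-extent of the street grid
    lon0: float = 2.35
    lat0: float = 48.85
    half_extent_m: float = 12_000.0
    grid_spacing_m: float = 500.0
    #: outer radii of the urbanicity rings (m)
    core_radius_m: float = 3_500.0
    close_radius_m: float = 7_500.0
    zone_shares: dict = field(default_factory=lambda: dict(DEFAULT_ZONE_SHARES))
    mode_mix: dict = field(default_factory=lambda: {z: dict(m) for z, m in DEFAULT_MODE_MIX.items()})
    speeds_kmh: dict = field(default_factory=lambda: dict(DEFAULT_SPEEDS_KMH))
    #: mean trips per surveyed day (Poisson, clipped to [1, 9])
    trips_per_day_mean: float = 4.6
    #: maximum walk from origin to a boarding station, by transit mode (m)
    access_max_m: dict = field(default_factory=lambda: {
        "bus": 700.0, "tramway": 900.0, "metro": 1200.0, "suburban_train": 3000.0,
    })
    #: probability that a rail trip gains a feeder bus leg (multi-mode trips)
    feeder_bus_prob: float = 0.25
    sensor: SensorConfig = field(default_factory=SensorConfig)

    def validate(self) -> "WorldParams":
        if self.grid_spacing_m <= 0 or self.half_extent_m <= self.grid_spacing_m:
            raise ConfigurationError("grid_spacing_m/half_extent_m inconsistent")
        if not 0 < self.core_radius_m < self.close_radius_m < self.half_extent_m:
            raise ConfigurationError("zone radii must be increasing and inside the region")
        if abs(sum(self.zone_shares.values()) - 1.0) > 1e-9:
            raise ConfigurationError("zone_shares must sum to 1")
        for zone, mix in self.mode_mix.items():
            if zone not in ZONES:
                raise ConfigurationError(f"mode_mix has unknown zone {zone!r}")
            if any(w < 0 for w in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"mode_mix[{zone}] must be a probability vector")
        if self.trips_per_day_mean <= 0:
            raise ConfigurationError("trips_per_day_mean must be > 0")
        if not 0.0 <= self.feeder_bus_prob <= 1.0:
            raise ConfigurationError("feeder_bus_prob must lie in [0, 1]")
        self.sensor.validate()
        return self


@dataclass
class PipelineConfig:
    """Tunables of the algorithmic GPS processing chain."""

    speed_threshold_kmh: float = 1.0       # low-speed point filter
    dwell_min_s: float = 300.0             # minimum stay duration for a visit
    visit_radius_m: float = 50.0           # stay-point radius
    smooth_window: int = 5                 # rolling-median window (points)
    walk_speed_boundary_kmh: float = 7.0   # walk / vehicle split boundary
    min_stage_s: float = 60.0              # shorter runs merged into neighbours
    station_snap_m: float = 75.0           # station proximity radius
    #: mode-score weights: speed band, station evidence, habitual-mode prior
    w_speed: float = 0.5
    w_station: float = 0.35
    w_prior: float = 0.15
    #: speed bands (km/h, half-open) per algorithm mode
    speed_bands: dict = field(default_factory=lambda: {
        "walk": (0.0, 7.0),
        "bike": (7.0, 16.0),
        "bus": (7.0, 40.0),
        "tramway": (7.0, 40.0),
        "metro": (15.0, 50.0),
        "suburban_train": (30.0, 120.0),
        "car": (7.0, 130.0),
        "long_distance": (130.0, 1000.0),
    })
    long_distance_min_km: float = 20.0
    #: survey-correction knobs
    iou_match_threshold: float = 0.5
    clean_corridor_m: float = 60.0
    recall_prob: float = 1.0
    recall_noise_sd_s: float = 0.0

    def validate(self) -> "PipelineConfig":
        if self.speed_threshold_kmh < 0:
            raise ConfigurationError("speed_threshold_kmh must be >= 0")
        if self.dwell_min_s <= 0 or self.visit_radius_m <= 0:
            raise ConfigurationError("dwell_min_s and visit_radius_m must be > 0")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ConfigurationError("smooth_window must be an odd positive integer")
        if not 0.0 <= self.recall_prob <= 1.0:
            raise ConfigurationError("recall_prob must lie in [0, 1]")
        if self.recall_noise_sd_s < 0:
            raise ConfigurationError("recall_noise_sd_s must be >= 0")
        if not 0.0 < self.iou_match_threshold <= 1.0:
            raise ConfigurationError("iou_match_threshold must lie in (0, 1]")
        return self


def _apply(obj, data: dict, path: str):
    for key, value in data.items():
        if not hasattr(obj, key):
            raise ConfigurationError(f"unknown config field {path}{key}")
        current = getattr(obj, key)
        if isinstance(value, dict) and not isinstance(current, dict):
            _apply(current, value, f"{path}{key}.")
        else:
            setattr(obj, key, value)


def load_config(path) -> tuple[WorldParams, PipelineConfig]:
    """Read a single YAML file with optional ``world`` / ``pipeline`` sections."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    world = WorldParams()
    pipe = PipelineConfig()
    _apply(world, data.get("world", {}), "world.")
    _apply(pipe, data.get("pipeline", {}), "pipeline.")
    return world.validate(), pipe.validate()
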