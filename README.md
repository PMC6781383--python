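# tripwalk

Measuring walking in multimodal trips from GPS tracking, hip-worn
accelerometry, and a prompted-recall mobility survey — with a synthetic
study world standing in for confidential cohort data.

## Who this is for

Transport-and-health researchers who combine logging GPS receivers
(~one fix every 5 s), accelerometers (per-epoch vector-magnitude counts and
steps), and a phone-administered, GPS-based mobility survey to build a
validated **timetable** of each surveyed day: visits to places alternating
with trips, trips decomposed into unimodal **trip stages** separated by
punctual **transfer episodes**. From that timetable the package computes
the quantities such studies report: distance walked and steps taken per
trip and per participant-day by travel-mode class, the percentage of all
transport walking attributable to each class (in particular to public
transport), walking intensity (speed, cadence) with distance/duration
weighting, urbanicity stratification, and the accuracy of algorithm-only
GPS processing against the survey-validated reference.

## The measurement chain

Raw GPS streams overstate travel (stationary indoor scatter generates
"pseudo-ambulation" over fake kilometres), miss trips (receiver left at
home, underground rides), and carry no trustworthy mode labels. The chain
is therefore:

1. **`gps_pipeline`** — drop fixes below 1 km/h (greedy, against the last
   retained fix, with a 300-s anchor reset), detect visited places as stay
   points (≥ 300 s within 50 m), extract the moves between them, split each
   move into candidate unimodal stages at smoothed-speed band crossings
   snapped to transit stations.
2. **`mode_imputation`** — score each stage s for every mode m:

   `score(m | s) = 0.5 · band(m, v̂ₛ) + 0.35 · station(m, s) + 0.15 · prior(m)`

   where `band` tests the stage's median smoothed speed against per-mode
   speed bands, `station` is 0.7 when stations of mode m lie within 75 m of
   both stage endpoints (1.0 when they share a line), and `prior` is the
   participant's habitual-mode weight from the baseline survey.
3. **`survey_correction`** — emulate the phone interview against ground
   truth: remove spurious visits/trips, recreate missed trips as shortest
   street-network paths, clean residual artefacts within a 60 m corridor,
   validate modes and timestamps. The timetable tiles each surveyed day
   exactly.
4. **`accel_link`** — Choi-style nonwear detection on vector magnitude
   (90-min zero window, ≤ 2-min interruptions flanked by ≥ 30 min of
   zeros) and exact step-to-segment joining by epoch midpoint.
5. **`trip_classification` / `metrics_report`** — crude and detailed trip
   classes with the multi-mode rule (walking never creates multi-modality),
   analytic exclusions (ski voids the whole sequence; jogging/dog-walking
   stages are cut with their adjacent transfers), trip-level nonwear
   flagging, and all headline tables: weighted quantiles (inverse-CDF),
   attribution shares, walking intensity, Kruskal–Wallis tests,
   urbanicity strata.

`synthetic_world` generates the stated world all of this is tested on:
a gridded region with zoned transit supply, multi-day ground-truth diaries,
and both sensor streams with switchable artefact channels (visit scatter,
pseudo-ambulation bursts, trip dropouts, metro tunnels). See
`docs/methods.md` for the model, defaults, and what the generator does
*not* emulate.

## Worked example

```python
from tripwalk.config import WorldParams, PipelineConfig
from tripwalk.pipeline import run_study
from tripwalk.metrics_report import attribution_shares, walking_intensity

res = run_study(WorldParams(), PipelineConfig(), 6, 7, seed=42)
print(res.distances.summary.round(1))
```

```
        quasi_raw_km  algorithm_km  survey_km
median          64.1          24.2       18.1
p10             39.5           4.5        3.7
p90            100.8          56.0       42.3
```

The three columns are the same participant-days measured three ways:
quasi-raw GPS (speed-filtered fixes only), algorithm-extracted trips, and
the survey-validated timetable. The raw median is ~3.5× the validated one —
that gap *is* the pseudo-ambulation artefact; the algorithm removes most of
it, the survey the rest (while also adding back trips the GPS missed).

```python
acc = res.accuracy
print(f"mode accuracy {100*acc.mode_accuracy:.1f}%")
print(attribution_shares(res.metrics, "distance_walked").round(1))
print(walking_intensity(res.trips)["speed_median"].round(1))
```

```
mode accuracy 94.5%            # walk 100%, public transport 92%
crude_class
entirely_walked      66.6
other_active          0.0
private_motorized     0.0
public_transport     33.4      # % of all distance walked, by trip class
entirely_walked         5.2
public_transport_all    5.5    # access walks to stations are brisker
pt_bus_coach            6.0
pt_metro                5.6
pt_suburban_train       5.5
pt_tramway              5.9
```

A third of all walking happens inside public-transport trips, and walking
to/from stations is faster than errand walking — the central pattern this
kind of measurement chain exists to expose. (On synthetic data these are
qualitative orderings, not cohort estimates.)

A command-line interface wraps the same calls:

```sh
tripwalk simulate -n 5 -d 7 --seed 1 --out-dir sim/     # GPX/CSV/GeoJSON
tripwalk segment sim/P000_gps.csv --out segments.geojson
tripwalk report -n 10 -d 7 --seed 1 --out-dir report/   # all tables as CSV
```

## Acceptance script

`scripts/acceptance.py` re-runs the whole chain from scratch — generates a
12-participant × 7-day world, executes the algorithm, survey and
accelerometer layers, and recomputes every reporting surface (three-way
distances, mode agreement, attribution shares, intensity summaries,
urbanicity strata, and the surveyed-day bookkeeping):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It prints a run log and writes the results file.
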