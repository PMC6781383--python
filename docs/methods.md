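# Methods

## The measurement problem

Quantifying walking in daily travel — including the walking embedded in
public-transport trips — requires more than a GPS track. Raw logging-GPS
streams inflate distances through stationary scatter ("pseudo-ambulation"
while the receiver sits indoors), lose trips entirely when the receiver is
left behind or rides underground, and carry no reliable travel-mode labels.
`tripwalk` implements a three-layer measurement chain modelled on
prompted-recall mobility-survey practice:

1. **algorithm-only GPS processing** — a 1 km/h low-speed filter, stay-point
   visit detection, trip extraction, and segmentation of each trip into
   candidate unimodal stages;
2. **mode imputation** — each stage scored against every mode from its
   smoothed speed, transit-station proximity at its endpoints, and the
   participant's habitual-mode weights;
3. **survey correction** — an emulated phone interview that confirms or
   removes detected visits and trips, recreates missed trips as shortest
   street-network paths, cleans residual track artefacts within a corridor,
   and validates modes and timestamps, yielding a *timetable*: visits, trip
   stages and punctual transfer episodes tiling each surveyed day exactly.

Accelerometer epochs (vector-magnitude counts and steps) are screened for
nonwear and joined to the timetable by epoch midpoint, so that distance
walked (polyline length of walking stages) and steps taken (over whole
trips, transfers included) can be tabulated by trip class, attributed as
percentage shares, and stratified by residential urbanicity.

Because the cohort data such a chain is normally run on are confidential,
the package ships a first-class synthetic world whose ground-truth diaries
make every layer testable.

## The synthetic world

**Region.** A 24 km square street grid (500 m spacing) centred on a
Paris-like coordinate, with three urbanicity rings: core city (< 3.5 km),
close suburb (< 7.5 km), far suburb. Transit lines run along grid axes with
mode-typical station spacing (metro 600 m, tram 500 m, bus 450 m, suburban
train 2.5 km); metro and tram do not reach the far suburb; stations are
offset 60 m from the street axis so access walks are never degenerate.

**Diaries.** Each participant (residence zone drawn 35/45/20) makes a
Poisson(4.6) number of trips per day (clipped to 1–9), mostly as
out-and-back tours from home; days tile `[0, 86 400)` exactly with visits
alternating with trips. Trip modes are drawn from a zone-specific mixture
(walking and PT dominate the core; the car the far suburb); infeasible
draws (no station in reach) are redrawn from the full mixture so realized
shares track the configured mixture. A public-transport trip is
walk → transfer → ride → transfer → walk, with station-dwell stop-and-go
folded into the ride schedule and an optional feeder-bus leg (25% of rail
trips) creating multi-mode trips. Access walks are brisker (5.2 km/h,
cadence 87/min) than errand walking (4.8 km/h, 84/min) — the
schedule-pressure contrast the metrics layer is expected to preserve.
Jogging and dog-walking are out-and-back loops; ski, coach and long-distance
modes exist in the alphabet (and in the exclusion rules) but default to
zero probability.

**Sensors.** GPS: one fix every 5 s in motion, 30 s at rest. Artefact
channels, all switchable and all off under `SensorConfig.noise_free()`:

| channel | default | what it emulates |
|---|---|---|
| visit scatter | AR(1), sd 15 m, 5% multipath jumps at 2 sd | indoor reception; what passes the 1 km/h filter |
| pseudo-ambulation burst | 50% per visit, OU walk sd 80 m, 10–40 min | fake indoor kilometres |
| in-trip jitter | AR(1), sd 5 m | correlated GPS error (white noise would double apparent walking speed) |
| trip dropout | 5% per trip | receiver left at home |
| metro visibility | 30% per ride | tunnels; the realistic cause of poor PT detection |

Accelerometer: 60 s epochs aligned to midnight; per-epoch steps drawn from
the cadence model of the diary context at the epoch midpoint (truncated
normal, sd scaled by √minutes); vector magnitude is context-scaled with a
20% chance of a literal-zero sedentary epoch, and exactly zero outside the
wear window (06:30–22:30), so the nonwear detector has honest input.

The generator does **not** emulate: HDOP-dependent error, urban-canyon
multipath structure, transit timetables/headways, parking-access walks for
car trips (car trips are door-to-door, so the private-motorized share of
walking is 0% here, unlike a real cohort), indoor transfer-corridor
geometry, or recall errors other than Gaussian timestamp noise. A green
test therefore establishes internal correctness of the chain and the
qualitative phenomenology above — not numeric agreement with any real
cohort.

## Numerical and algorithmic choices

- **Distances** are haversine over consecutive polyline vertices; a local
  equirectangular projection is used only for geometry construction and
  corridor distances.
- **Low-speed filter**: greedy single pass retaining fixes at ≥ 1 km/h
  relative to the previously *retained* fix, plus an **anchor reset**: a fix
  arriving more than 300 s after the retained predecessor is always kept.
  Without the reset the speed reference goes stale during long stationary
  spells and the start of every subsequent trip is swallowed. The pass is
  idempotent.
- **Visit detection**: maximal runs staying within 50 m of their running
  centroid for ≥ 300 s; a silent gap ≥ 300 s is itself a visit (signal
  loss); consecutive co-located visits merge — absorbing pseudo-ambulation —
  only when the intervening movement stays within 6× the radius, which
  preserves genuine out-and-back loops. Visits and moves tile the observed
  span exactly.
- **Stage splitting**: centred 5-point rolling-median speeds, cut at the
  7 km/h walk/vehicle boundary, runs shorter than 60 s merged into the
  longer neighbour, cuts snapped to the in-window fix nearest a transit
  station (within 75 m). Output intervals partition the move exactly.
- **Mode scores**: `0.5·band + 0.35·station + 0.15·prior` with the default
  bands walk [0,7), bike [7,16), bus/tram [7,40), metro [15,50), suburban
  train [30,120), car [7,130) km/h; station evidence 0.7 for mode-matched
  stations at both endpoints, 1.0 when they share a line; deterministic
  tie-break by fixed mode order. Driver vs passenger is left to the survey.
  Long-distance requires > 130 km/h *and* ≥ 20 km.
- **Agreement report**: durations by exact interval intersection; transfer
  episodes are excluded from every denominator (their timestamps are the
  least reliable part of the timeline) and the report flags this.
- **Survey matching**: algorithm moves match truth trips at interval
  IoU ≥ 0.5 (greedy, best-first). Matched stages keep algorithm geometry
  sliced to the validated stage interval, cleaned within a 60 m corridor
  (> 50% artefactual vertices ⇒ wholesale redraw onto the reference), and
  anchored at the validated endpoints (manual complementation of missing
  track heads/tails). Missed trips are recalled with probability 1.0 by
  default; recreated walk/bike/car legs use the shortest grid path
  (lexicographic tie-break), transit legs the line itinerary; an unrecalled
  trip extends the preceding visit. Timestamp noise perturbs internal
  boundaries jointly, so the day still tiles exactly.
- **Nonwear**: zero-vm runs ≥ 90 min, allowing interruptions ≤ 2 min
  flanked by ≥ 30 min of zeros, evaluated on the package's epoch grid
  (an approximation of the vendor 1-s implementation; epoch length is
  configurable for sensitivity analysis).
- **Step joining**: epoch midpoint assignment — deterministic and exactly
  conservative because the timetable tiles each day. Steps per 8 h of wear
  divide by wear seconds / 28 800 (surveyed days contain nonwear, so days
  cannot be the denominator).
- **Quantiles**: inverse-CDF weighted quantiles (smallest value whose
  cumulative normalized weight reaches the probability); unweighted
  summaries use unit weights so the two definitions agree by construction.
  Walking speed summaries weight stages by distance walked; cadence
  summaries by duration walked. Per-day cumulations by class zero-fill
  participant-days that do not use the class.
- **Kruskal–Wallis**: rank-sum H with tie correction, p from χ²(k−1);
  all-identical input returns H = 0, p = 1.
- **Exclusions**: a ski/chairlift stage voids its whole movement sequence;
  jogging/dog-walking stages are cut with their adjacent transfers and the
  trip survives (re-classified) if stages remain; long-distance train and
  plane stages are transport and stay. Per-day medians pool
  participant-days (not participant means) — documented choice where the
  tabulation convention is ambiguous.

## Known limitations

- Transfer-episode cadence is reported separately and flagged
  low-confidence (`transfer_cadence`): transfer timestamps mix true waiting
  with timestamping error.
- The mode-imputation layer cannot tell bike from car without station or
  prior evidence (overlapping bands); bike accuracy is poor by
  construction, as in the field.
- Timetables of recreated trips reuse ground-truth timestamps plus noise; a
  real deployment with no GPS at all needs a different timestamping rule.
- The classification ledger of a real study (initial trips → analytic
  trips) involves survey-editor judgements this emulation does not model;
  the package documents its own ledger instead.
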