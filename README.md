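# sleepverse

Multiverse analysis of smartphone-sensed sleep: from raw per-participant
sensor event streams (accelerometer x-axis, charging state, ambient
light, activity-recognition labels, screen on/off, Wi-Fi connection) to
per-night sleep/wake grids, derived sleep features, outlier handling,
and single-predictor models of morning subjective sleep quality (SSQ),
daily negative affect (NA) and person-level depression — evaluated over
the full 12,600-point grid of analysis choices with a hold-out 1-SE
selection workflow.

Because no participant dataset is available, the package includes a
first-class synthetic-data generator with known ground truth (true bed
and wake times, nightly interruptions, outcomes linear in the true
sleep features), so every pipeline stage is testable by construction
and by parameter recovery.

## Pipeline

1. **synthetic** (`sleepverse.synthetic`) — seeded generator: true
   sleep schedules, six sensor event streams that recover them under
   the sleep-indication rules when noise is off, and linked outcomes.
2. **ingest** (`sleepverse.ingest`) — long-format sensor-event CSV and
   outcome CSV readers/writers with exhaustive reject reports.
3. **preprocess** (`sleepverse.preprocess`) — sparse/dead stream
   removal, boxplot gap-outlier removal, per-participant accelerometer
   centering, <12 s screen-flash filtering, and per-instant sleep/wake
   classification for the 10 sensor configurations (3 accelerometer
   thresholds, 3 light thresholds, charging, activity, screen, Wi-Fi).
4. **windows** (`sleepverse.windows`) — 144 five-minute windows per
   night (10 PM–10 AM), majority vote per window, carry-forward.
5. **features** (`sleepverse.features`) — BedTime/WakeUpTime run
   detection (k ∈ {3,4,5} adjacent windows) and the seven per-night
   features: SleepTime, devAvgBedTime, devAvgWakeUpTime,
   nInterruptions, InterruptionsDuration, TotalSleep, UserActive.
6. **outliers** (`sleepverse.outliers`) — none, median ± 3 SD,
   median ± 3 MAD (both per participant), pooled isolation forest.
7. **models** (`sleepverse.models`) — mixed-effects (random intercept;
   linear model for depression), kNN, radial SVM, gradient boosting,
   spline GAM; predicted R² = 1 − SSE/SST on held-out data.
8. **multiverse** (`sleepverse.multiverse`) — grid enumeration
   (10·7·3·5·4·3 = 12,600), week-1 train / days 8–11 validation /
   days 12–14 test split (gender-stratified 60/20/20 participant split
   for depression), 1-SE selection (bootstrap SE, max 5 models per
   outcome), test-set evaluation of selected models only.
9. **report** (`sleepverse.report`) — feature-robustness and R²
   distribution tables, mixed-model/Pearson correlation analysis with
   Benjamini–Hochberg correction, boxplot figures.

## CLI

```sh
# generate a synthetic study (events.csv + outcomes.csv)
sleepverse simulate --seed 1 --n-participants 20 --days 14 --out-dir data/

# run a (restricted) multiverse sweep; --resume skips finished configs
sleepverse multiverse --events data/events.csv --outcomes data/outcomes.csv \
    --config grid.yaml --out results.csv --seed 1

# summarize a sweep
sleepverse report --results results.csv --out-dir report/
```

`grid.yaml` may restrict any multiverse axis, e.g.:

```yaml
outcomes: [ssq]
models: [mixed_effects]
outliers: [none, median_3mad]
```

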