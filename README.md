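# gaitval

Validity, reliability and interpretability analysis for paired-system 3D
lower-limb gait kinematics: a wearable inertial (IMU) system evaluated
against a camera-based optoelectronic (OPTO) reference.

The package covers the full evaluation pipeline:

- **`gaitval.datamodel_io`** — domain types (101-point time-normalized angle
  cycles over 11 kinematic outcomes, subject/session/operator keys),
  long-format cycles CSV reader/writer, JSON configuration.
- **`gaitval.synthetic_gait`** — seeded synthetic cohorts (three groups:
  asymptomatic AS, cerebral palsy CP, other motor disorders OMD) with a
  controlled between-system error structure (constant per-outcome offsets —
  15° at pelvic tilt by default — plus waveform noise), raw walking trials
  with ground-truth gait events, and wand-drop synchronization trials.
- **`gaitval.signal_prep`** — offline clock synchronization from sync-trial
  impacts, coordinate-based gait event detection (heel/toe relative to the
  sacrum along the progression axis), gyro-based event detection from the
  sagittal foot angular velocity, and segmentation into 101-point cycles.
- **`gaitval.validity`** — per-cycle agreement metrics (RMSE, centered RMSE,
  Pearson correlation, |ΔROM|, relative RMSE), aggregation cycle → subject →
  group with 95% confidence intervals, correlation-band interpretation, and
  RMSE-vs-gait-profile-score correlation.
- **`gaitval.reliability`** — discrete curve parameters (max/min/ROM/mean),
  intra-operator (session 1 vs 2) and inter-operator (A vs B, session 2)
  designs, and ICC from REML variance components of a two-way mixed model
  (exact closed form for the balanced two-condition design, ANOVA
  method-of-moments fallback), with reliability-band interpretation.
- **`gaitval.gps_interpret`** — per-system normative banks (asymptomatic
  group means), gait variable scores and gait profile scores (GPS), paired
  between-system tests, group comparisons, minimal-detectable-change flags
  and Tukey outlier detection.
- **`gaitval.cli`** — `simulate` / `analyze` / `report` subcommands.

## CLI

```sh
# generate a synthetic cohort (cycles CSV + raw walk + sync trials + truth)
gaitval simulate --out runs/sim --seed 1

# run all analysis stages on the cycles table (and signal prep on the raw set)
gaitval analyze --cycles runs/sim/cycles.csv --raw runs/sim --out runs/analysis

# print the rendered markdown report
gaitval report --analysis runs/analysis
```

`analyze` writes `validity_summary.csv`, `reliability_icc.csv`,
`gps_report.csv`, `rmse_gps_correlation.csv`, `events.csv` (raw route),
`report.md` and a `manifest.json` run manifest. Reliability is skipped with
a warning (exit 0) when the cohort lacks the repeated-session/operator
design. Exit codes: 0 success, 2 validation error, 3 data/pairing error.

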