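# herdsense

Sensor-based feeding and rumination phenotyping of group-housed dairy
cows, built around a fully synthetic barn. The package provides an
end-to-end, reproducible pipeline from raw sensor streams to behavioral
phenotypes and lameness-effect models:

- **`herdsense.synthgen`** — synthetic barn generator: a mixed-parity
  cohort (7 non-lame + 9 lame cows by default), feed-station visit
  streams (12 stations, 5 kg/visit cap with occasional override, daily
  station-reset window with unassigned intake), per-day milk yields,
  a rumination event schedule, and labelled contamination (zero-duration
  visits, sub-4 s visits with intake, off-line intake outliers).
- **`herdsense.rumclass`** — 12 Hz tri-axial accelerometer synthesis
  from labelled activity schedules, windowed variance + Fourier band
  power features, Gaussian-emission HMM segmentation (Viterbi), event
  reconstruction, and window-level sensitivity/PPV evaluation.
- **`herdsense.feedclean`** — two-pass cleaning of feed-station visits:
  per-cow origin regression of intake on duration, ±5 SD outlier rules,
  sub-4 s/&gt;0.1 kg rule, refit, and case-based replacement of intake or
  duration from the second regression.
- **`herdsense.features`** — daily characteristics (intake, feeding
  time/frequency/rate, per-visit means, rumination time/frequency/event
  duration, milk), per-cow feeding-rate slopes, lameness categorization
  from four locomotion scores, inter-/intra-individual CV decomposition,
  and reset-window mass-balance helpers.
- **`herdsense.lmm`** — linear mixed models with one random effect per
  cow (intercept or slope), fitted by profiled (RE)ML with exact rank-1
  Woodbury updates; likelihood-ratio tests, stepwise interaction
  reduction, RSS-based R², AIC/BIC comparison tables, and least-square
  means.
- **`herdsense.cli`** — the `herdsense` command-line pipeline.
- **`herdsense.recovery`** — seeded parameter-recovery studies used by
  the acceptance report.

## Command line

```bash
# full pipeline: simulate -> clean -> daily features -> CV table -> models
herdsense all --seed 1 --days 22 --out out/run1

# individual stages
herdsense simulate --seed 1 --days 22 --out out/barn
herdsense clean --visits out/barn/visits.csv --out out/cleaned.csv \
    --report out/report.json --sd-k 5
herdsense features --visits out/cleaned.csv \
    --rumination out/barn/rumination_truth.csv --milk out/barn/milk.csv \
    --cohort out/barn/cohort.csv --out out/daily.csv --cvtable out/cv.csv
herdsense model --daily out/daily.csv --visits out/cleaned.csv \
    --cohort out/barn/cohort.csv --out out/models.json
herdsense classify --truth out/barn/rumination_truth.csv --cow 3 --day 2 \
    --seed 1 --out out/events.csv
```

`herdsense all` writes `daily.csv`, `cvtable.csv`, `models.json`,
diagnostic figures, and a `manifest.json` with the config hash and seed;
re-running with the same config and seed reproduces `daily.csv` byte for
byte. Exit codes: 0 ok, 1 input error, 2 convergence failure.

Generator configuration is a YAML file (see
`herdsense.config.GeneratorConfig`); group-level trait means/SDs default
to published group-level values for a 16-cow cohort and every knob
(contamination rates, cap-override probability, couplings, trends) is
overridable.

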