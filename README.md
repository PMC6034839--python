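# tumorclock

A deterministic exponential-growth model of the whole natural history of a
primary breast tumor (PT) and its secondary distant metastases (MTS) on a
shared 60-volume-doubling clock.

The model: a tumor grows from a single 10 µm founder cell by repeated volume
doublings (diameter × 2^(1/3) per doubling). At the PT's 20th doubling
(~1 mm, ~10⁶ cells) the first distant metastatic cell is seeded; it grows at
the same rate. Death corresponds to the metastasis completing the remaining
40 doublings (~103 mm). A single pre-surgery PT diameter — or a doubling
time estimated from two serial scans via the classical two-point (Schwartz)
estimator — therefore fixes the entire timeline: occult and visible PT
growth, occult MTS growth before and after surgery, the visible MTS period,
and the post-surgery survival interval. Only node-negative (N0) disease is
described.

## Layout

| Module | Contents |
|---|---|
| `tumorclock.growth` | diameter ↔ doubling ↔ cell-count conversions, Schwartz doubling-time estimator, `ModelConstants` |
| `tumorclock.staging` | size-based T classification (T1a–T3), per-stage doubling times, loadable stage table |
| `tumorclock.natural_history` | full timeline decomposition, calendar anchoring, growth-curve sampling |
| `tumorclock.prognosis` | forecast bands and relapse-risk groups from the occult post-surgery MTS period |
| `tumorclock.cohort` | synthetic-patient generator with noisy serial measurements + parameter recovery |
| `tumorclock.report` | per-stage summary tables with display rounding and reference diffing |
| `tumorclock.cli` | `tumorclock` command-line interface |

## CLI

```sh
# timeline, prognosis and risk group for one patient
tumorclock timeline --diameter 15.1
tumorclock timeline --diameter 15.1 --tvdt 60 --format json

# doubling time from two serial measurements
tumorclock tvdt --d0 5 --d1 10 --days 210

# regenerate the per-stage tables; --diff compares to the published values
tumorclock tables
tumorclock tables --diff

# synthetic cohort + recovery summary
tumorclock simulate --n 500 --noise 0.05 --seed 42 --out-csv cohort.csv

# growth-curve series (CSV) for both lesions on the shared clock
tumorclock curve --diameter 28.5 --out curve.csv
```

Model constants (founder diameter, seeding doubling, visibility thresholds,
…) can be overridden with `--config file` where the file holds flat
`key = value` lines. Exit codes: 0 on success, 2 on usage/domain errors.

## Known reference-table discrepancies

Two published period cells disagree with direct computation by exactly one
unit in the last printed digit and are documented in the tests: the occult
MTS-I entry at T1c (printed 2.3, copies the visible-PT row; the true
seeding→surgery period computes 2.24) and the T2 survival entry (printed
4.5, contradicting its own row sum 2.7 + 1.9; computes 4.55).
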