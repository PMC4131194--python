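# gcio — granule-cell input–output gain analysis

`gcio` is a tested pipeline for analyzing the input–output (f–I) gain of
dentate granule cells recorded in current clamp: from raw sweep bundles to
per-cell gain statistics to the population-level question of whether the
cohort splits into two functional groups ("Sensitive" vs "Linear"). Because
raw recordings of this kind are rarely deposited, the package ships a
first-class synthetic cohort generator (curve-level and exponential
integrate-and-fire trace-level) with retained ground truth, used both for
testing and for power analysis.

## What it computes

**Per-sweep / per-cell features** (`gcio.ephys_features`)

- Spike detection: upward crossings of 20 mV/ms in the derivative of the
  4 kHz zero-phase low-pass-filtered voltage; threshold voltage at the
  crossing, peak dV/dt from the unfiltered derivative.
- Input resistance from the mean steady-state response to −10 pA steps
  (sweeps with large spontaneous events excluded), membrane time constant
  from single-exponential fits 2–100 ms after step onset/offset (averaged),
  resting potential from pre-stimulus baselines, whole-cell capacitance from
  the charge of a −5 mV voltage-clamp step.
- Excitability from an incrementing (Δ20 pA) square family run until
  depolarization block: AP threshold and peak dV/dt from the first spike at
  the lowest spiking amplitude, maximal firing rate before block.
- QC: cells excluded when the resting potential drifts > 4 mV or when the
  input resistance is < 90 MΩ (semilunar granule cells).

**Gain statistics** (`gcio.io_features`) — from sinusoidal drive
(5/10/20/40/60/80 Hz, 50 pA amplitude increments, 1 s per sweep):

- input–output curve = spike count vs peak amplitude, masked for lack
  (leading zeros) and saturation (tail from the first non-increase);
- `asl_f = mean(Δcounts) / √f` (average slope, the gain),
- `var_f = var(Δcounts, ddof=1) / f` (sensitivity to narrow input ranges),
- `offset_f = A* / f^(1/4)` with `A*` the smallest amplitude whose count
  exceeds f/2;
- pooled per-cell values = arithmetic mean over defined frequencies.

Note the weighting direction ("weighted by √f") is ambiguous in the source
description; this implementation **divides** by the weight, which yields
pooled slopes of order 1–2, matching the published cluster centers.

**Population inference** (`gcio.population_stats`)

- one- vs two-component Gaussian fits to the histogram (Poisson-weighted
  least squares) compared by an extra-sum-of-squares F-test;
- K-means (k=2) with per-cluster centers/mean distances and one-way ANOVA
  separation p; a `GaussianMixture` BIC cross-check;
- Ward hierarchical clustering on the seven z-scored intrinsic parameters
  (RMP, τ_M, C_m, R_in, threshold, peak dV/dt, max rate) with agreement vs
  the functional labels (best-permutation accuracy, adjusted Rand index);
- weekly age-binned S/L probabilities, parabolic mean–variance fits, and
  per-group OLS of each gain statistic on input resistance.

**Synthetic cohorts** (`gcio.synthetic_cohort`)

- tier `curves`: per-frequency count curves with exact generating increment
  mean/variance per cell; S cells concentrate their dynamic range in one
  dominant increment, L cells rise by near-constant increments;
- tier `traces`: EIF sweeps (Euler–Maruyama, 0.02 ms) under the full
  protocol set, with ground-truth spike times attached;
- age-dependent group probability (all S at 21 d, all L by 70 d),
  group-independent intrinsic-parameter drift, offset tied to R_in in both
  groups, slope tied to R_in in the L group only.

## CLI

```bash
# synthetic cohort -> features -> population report, in one step
gcio all --seed 7 --out results/ --n-cells 120 --stat asl

# stage by stage
gcio simulate --seed 7 --n-cells 4 --tier traces --out cohort/
gcio features --bundle cohort/cell0000 --bundle cohort/cell0001 --out features.csv
gcio stats --features features.csv --stat asl --seed 7 --out report.json

# from a config file (JSON or YAML; "seed" is required)
gcio report --config config.json
```

`gcio all` writes `features.csv` (per-cell gain statistics + intrinsic
parameters + S/L labels), `per_frequency.csv`, `age_probabilities.csv`,
`exclusions.csv` (one row per excluded cell with reasons), `truth.csv` (for
synthetic runs) and `report.json`. Reruns with the same config and seed are
byte-identical.

## File formats

One bundle per cell, read/written by `gcio.trace_io`:

- **HDF5**: `/sweeps/<id>/{voltage,current}` float64 datasets, protocol and
  units as attributes;
- **CSV+JSON**: a directory with `manifest.json` plus one
  `voltage_mV,current_pA` CSV per sweep — diffable and byte-stable across
  write→read→write round trips;
- **NWB**: optional read-only import when `pynwb` is installed.

Units are normalized to mV / pA / kHz on read; files without unit
declarations are rejected.

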