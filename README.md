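# fallbench

Benchmark of four wearable-sensor fall-detection algorithms on tri-axial
accelerometer + gyroscope (IMU) recordings, together with the
cross-validated random-search/ROC protocol used to pick their thresholds
and a Friedman/Nemenyi framework for comparing them. A seeded synthetic
fall/ADL signal generator makes the whole pipeline runnable with no
external downloads.

## Algorithms

| Name | Idea |
|---|---|
| `alg1` | Two-phase (free-fall + impact) thresholds on the acceleration magnitude (SMV) and on the absolute vertical acceleration obtained from a complementary-filter orientation estimate |
| `alg2` | 2 s sliding window; cascade of five features (L1 acceleration SV, successive-sample angle, before/after orientation change, L1 angular velocity and angular acceleration) against thresholds |
| `alg3` | Pearson correlation of 5 s signal segments against a fall pattern, refined by gyroscope-template correlation (z-axis first, then y) |
| `alg4` | Finite state machine on SMV (impact peak + post-impact inactivity) proposing candidates; an 11-feature time/frequency vector around the peak is classified by kNN |

The kNN feature list is a documented stand-in (the original set is not
published); see `fallbench.fsm_knn.FEATURE_NAMES`.

## Layout

- `fallbench.signals` — data model (`ImuRecording`), CSV dialects
  (generic / MobiAct / DLR / UMAFall layouts), preprocessing chain
  (downsample to 50 Hz, 3-sample median), windowing.
- `fallbench.two_phase`, `feature_cascade`, `pattern_match`, `fsm_knn` —
  the four detectors (`alg1`–`alg4`).
- `fallbench.search` — search ranges, stratified 10-fold CV, random
  candidate sampling, ROC-distance selection, cumulative confusion matrix.
- `fallbench.evaluation` — sensitivity/specificity/precision/F1, the
  replicated-block Friedman rank table, Nemenyi post-hoc test, reports.
- `fallbench.synthetic` — seeded fall/ADL waveform generator and corpus
  assembly.
- `fallbench.cli` — `fallbench` command-line entry point.

## CLI

```sh
# 1. generate a synthetic corpus (CSV + JSON sidecars + manifest)
fallbench simulate --n-falls 50 --n-adls 50 --seed 7 --out corpus/

# 2. threshold search with 10-fold CV, 10 random candidate sets per fold
fallbench optimize --algorithm alg2 --dataset corpus/ --seed 7 --out alg2.json
fallbench optimize --algorithm alg4 --dataset corpus/ --seed 7 --out alg4.json

# 3. rank-based comparison across result files
fallbench compare --results alg2.json --results alg4.json --metric f1

# one-off detection with the published optimum thresholds
fallbench detect --algorithm alg1 --dataset corpus/
```

`optimize` output is a JSON file with per-fold winning thresholds, test
confusion matrices, the cumulative matrix, and per-fold metrics;
`compare` consumes any number of those files (grouped by dataset name)
and prints the Friedman table plus Nemenyi critical-distance results.

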