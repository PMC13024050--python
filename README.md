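# phytoaffect

Decoding environmentally defined valence–arousal regimes from internal
plant signals.

## The problem

Plants respond to their environment through coupled electrical and
metabolic dynamics. This package asks a decoding question: if we define
an *affect-adjacent* coordinate system purely from chamber conditions —
how favourable the regime is (**valence**) and how much physiological
activation it demands (**arousal**) — can a classifier recover those
coordinates from internal plant measurements alone (extracellular
bioelectric potential, eCO₂, TVOC), without ever seeing the
environmental variables?

It is aimed at researchers in plant electrophysiology / biosignal
analysis who want a fully tested, reproducible version of this analysis
that runs end-to-end on a bundled chamber-and-plant simulator, or on
their own CSV recordings.

## The model

Labels come only from the environment. With z-scored light `L`,
temperature `T` and humidity `H`, light is regressed on temperature and
humidity,

```
L = β₀ + β_T·T + β_H·H + ε,     L_res = ε
```

and the affect coordinates are the fixed linear combinations

```
V = L_res − T + H        (valence)
A = L_res + T − H        (arousal)
```

so valence rises with residual light and humidity and falls with
temperature, while arousal does the opposite — the vapour-pressure-
deficit logic of plant stress. Both are rolling-median smoothed,
binarised by sign (`v = 1[V>0]`, `a = 1[A>0]`) with a dead-zone around
the origin, and combined into a quadrant code `q = 2v + a`
(0:−−, 1:−+, 2:+−, 3:++). Samples with infrared readings below a
validity floor are masked.

Decoding operates on sliding windows summarised by per-channel mean and
standard deviation of the plant signals only. Two decoders share one
readout (closed-form ridge regression to ±1 targets, sigmoid-squashed
score thresholded at 0.5):

* a **windowed linear decoder** applied directly to the features, and
* an **Echo State Network**: a fixed random leaky reservoir
  `x(t+1) = (1−α)x(t) + α·tanh(W_in u(t) + W x(t))`
  (300 units, spectral radius 0.9, leak 0.2, input scaling 0.5, 50-step
  washout) fed one window per step, with only the ridge readout trained.

Evaluation uses forward-chaining time-series cross-validation (five
contiguous splits, per-training-fold standardisation, metrics on test
segments only) and reports balanced accuracy, F1 and majority baselines.
A circular-shift permutation null re-runs the identical pipeline with
labels rotated in time by at least a minimum lag, which collapses
genuine coupling to chance while preserving marginal label structure.

## Worked example

Simulate 48 h of chamber protocol (random 15–45 min heater episodes,
36 °C fan trigger holding a >35 °C stress band, 24 h flushes, diurnal
light, humidity anti-coupled to temperature), generate coupled plant
channels, and run the full decoding chain:

```bash
phytoaffect run-all --seed 1 --duration 48 --out demo/
```

prints

```
valence: balanced accuracy 0.787 +/- 0.129 (baseline 0.61)
arousal: balanced accuracy 0.852 +/- 0.144 (baseline 0.55)
quadrant_combined: balanced accuracy 0.599 +/- 0.068 (baseline 0.52)
quadrant_esn: balanced accuracy 0.734 +/- 0.123 (baseline 0.52)
```

Each line is the mean ± sd of balanced accuracy across the five
forward-chaining folds for one decoding task, against the majority-class
baseline of the pooled test windows. Valence (20 min windows, 15 min
stride) and arousal (1 min windows) are decoded well above baseline from
plant channels alone; four-way quadrant decoding beats its 0.25 chance
level, and the ESN's temporal continuity beats the static combined-binary
decoder. `demo/` also contains `metrics.json` (full per-fold metrics and
null results), labelled confusion-matrix CSVs, the generated traces, and
`trajectory.csv` — the affective-space trajectory in non-overlapping
7 min windows.

The same stages are available individually (`simulate`, `label`,
`windows`, `decode-linear`, `decode-esn`, `null`, `report`) and as
library functions (`phytoaffect.simulate_environment`, `build_labels`,
`make_windows`, `evaluate_pipeline`, `run_null`, ...), on synthetic or
user-supplied CSV traces.

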