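# Methods

This note documents the models, defaults and design decisions behind
`phytoaffect`, in the order the pipeline runs them.

## 1. Chamber simulator

`simulate_environment` produces a 0.5 Hz multichannel trace of a small
closed growth chamber under an active thermal protocol.

**Thermal model.** Temperature follows first-order relaxation toward
the ~25 °C ambient (time constant 300 s — a desk-scale acrylic chamber
leaks heat quickly), plus a heater term (target 55 °C, time constant
300 s, i.e. a pad strong enough to cross the 36 °C trigger within a few
minutes) and a fan term (target 28 °C, time constant 150 s). The fan
latches on when temperature reaches `fan_trigger_temp` (36 °C) and
releases at `fan_floor_temp` (35 °C), so during a heater episode the
chamber thermostats inside the 35–36 °C stress band with a roughly
one-minute cycle; this fast cycling is the chamber's dominant source of
sub-minute variance, and matters downstream (§4). A small
Ornstein–Uhlenbeck jitter models sensor noise and micro-drafts.

**Heater episodes.** Onsets form a memoryless (Poisson) process,
refractory while an episode is active; durations are uniform in
[`heater_min`, `heater_max`] = [15, 45] min. The onset rate defaults to
24/day: roughly hourly perturbation, enough to accumulate hundreds of
episodes over a multi-day recording while leaving the chamber unforced
most of the time. A fan flush runs for 5 min every 24 h.

**Light and infrared.** Light is a half-rectified diurnal sinusoid
(peak 400 sensor units at "midday") multiplied by a slow cloud factor
(OU, τ = 30 min) and a fast flicker factor (OU, τ = 90 s) — both
irradiance-proportional — plus a small heater-correlated component and
sensor noise, clipped at zero. Infrared is a warm-body channel
correlated with light and the heater pad; its baseline keeps ordinary
night readings above the downstream validity floor of 1, so the IR
filter removes only (simulated) sensor-failure-scale values, not
night-time.

**Humidity.** `humidity_base` (55 %RH) plus `humidity_temp_gain`
(−1.8 %RH/°C) times the temperature excursion plus smooth OU noise,
clipped to [0, 100]: hot air in a closed chamber reads drier, giving
the strong T–H anti-coupling that the label construction assumes.

All draws flow from one `numpy` generator seeded by `ChamberConfig.seed`;
identical configs give bitwise-identical traces.

## 2. Plant-signal generator

`simulate_plant` is a statistical stand-in, not a physiological model.
It first computes the *true* affect drives (V, A) from the true chamber
variables using the same construction as the labelling stage (so
labelling remains an honest, separate estimation step), then couples:

* **bioelectric** = `fast_gain` · high-pass(A, `tau_fast`) + white
  noise. The high-pass models sensory adaptation: sustained levels are
  adapted away over `tau_fast` = 1800 s, so the channel carries
  seconds-to-minutes content — heater onsets, thermostat cycling,
  light flicker — and encodes the hypothesis that arousal-related
  internal dynamics are fast.
* **eCO₂ / TVOC** = baseline (400 ppm / 50 ppb) + `slow_gain` ·
  low-pass(V, `tau_slow`) + random-walk drift + white noise. The leaky
  integrator (`tau_slow` = 90 min) models slow metabolic/emission
  responses to regime favourability; TVOC uses half the eCO₂ gain.
  `noise_sd_gas` defaults to 25 (metal-oxide gas sensors are noisy at
  the sample level; window means remain precise) and drift accumulates
  at 2 units/√hour, as such sensors drift on baseline.

Plant channels are generated directly on the 0.5 Hz environmental
timebase. A physical rig samples the electrode at 100 Hz, but every
downstream computation consumes window summaries, so the generator
produces the aggregated-scale signal directly; this changes data volume,
not the decoding problem.

**What passing tests do and do not show.** The generator reproduces the
*structure* of the recording — regime dynamics, timescale separation,
noise and drift — but none of the biology: no stomatal or photosynthesis
model, no action/variation-potential waveforms, no watering or
lid-removal artefacts. Recovery of the couplings here demonstrates that
the pipeline is correct and leak-free, not that real plants carry the
signal.

## 3. Labels

Full-trace z-scoring (population sd) of T, H, L; OLS of L on [1, T, H];
V = L_res − T + H, A = L_res + T − H; centred rolling median (default
15 min, odd sample count, shrinking at edges) wide enough to suppress
chamber-intervention transients; sign binarisation with a dead-zone
half-width of 0.1 z-units (the width is a package choice; only the
existence of a dead-zone is given); IR validity floor 1. Labels use
full-trace statistics deliberately — they are external ground truth, not
decoder features, so this is not leakage; decoder features are
standardised separately per training fold. Binarisation uses strict
`> 0`; exact zeros fall to class 0 and are masked whenever the dead-zone
is active.

## 4. Windows and features

Windows are half-open `[start, end)`, tiled at the stride from the first
sample, with one end-anchored window when the last regular window stops
short of the trace end. Features are per-channel mean and population sd
over *unmasked* in-window samples; windows below `min_valid_fraction`
(default 0.5) of valid samples are dropped. Window labels are majority
votes over unmasked per-sample binaries (exact ties dropped); a
mean-sign rule is available. Task geometries: valence 20 min/15 min
stride, arousal 1 min, quadrant and ESN 1 min, trajectory 7 min
non-overlapping.

Two different mechanisms make window length matter. Valence information
lives in the slow gas channels, so 20 min means are a good statistic.
Arousal information lives in the fast bioelectric channel; because
regimes last tens of minutes, 20 min windows frequently straddle regime
boundaries and their majority labels disagree with most of their
content, while 1 min windows are almost always regime-pure — the
timescale dissociation is therefore an *ordering* between the same
task at two geometries, not a property of either alone.

## 5. Decoders

Both decoders share one readout: closed-form ridge on `[X; 1]` with the
bias column unpenalised, targets encoded ±1, penalty 1.0, prediction by
sigmoid(score) thresholded at 0.5 (identically score > 0, with exact
zero falling to class 0). The linear decoder applies it to the
standardized features; the ESN first expands the feature sequence
through a fixed random reservoir (one step per window). Reservoir
choices: tanh activation (gives the [−1,1] state containment and echo
property), recurrent weights Uniform(−1,1) at density 0.1 rescaled to
spectral radius 0.9 exactly, dense input weights Uniform(−1,1) × 0.5,
leak 0.2, washout 50 steps discarded from readout training. The leak
rate and ridge penalty are distinct parameters despite the shared
symbol in common notation. Quadrant decoding fits independent valence
and arousal readouts (on features or on shared reservoir states) and
recombines q = 2v + a; degenerate (single-class) training folds are
skipped and logged.

During cross-validation the ESN state is carried causally from the end
of the training segment into the test segment: test states depend on
training history (legitimate — it is the past) but never the reverse.

## 6. Evaluation and null

Forward-chaining splits mirror scikit-learn's `TimeSeriesSplit` (five
contiguous tail test blocks, expanding training windows, remainder to
the initial training segment); an assertion enforces
max(train) < min(test) in every fold before any fit. Balanced accuracy
(mean per-class recall, zero-support classes excluded with a warning),
per-class/macro F1 (0 convention when P+R = 0) and the majority
baseline are computed from confusion matrices. Fold-mean ± sd is the
headline view; pooled-confusion metrics are reported alongside because
the two legitimately differ. Reports round to 3 decimals (baselines
also at 2).

The circular-shift null rotates the *window-level* label sequence (in
units of strides) and re-runs the identical fold plan, standardisation
and decoder, so the feature set is exactly shared between real and null
runs and label alignment is the only difference. Shifts are drawn
uniformly with at least `min_shift` of rotation in both circular
directions (valence ≥ 360 min, arousal ≥ 60 min by default — both well
beyond the 90 min longest coupling memory); shifts producing any
single-class training fold are discarded and resampled within a bounded
retry budget. Raw-sample shifting before windowing is equivalent when
the shift is a multiple of the stride (tested), so the window-level
default loses no generality for the shifts used.

## 7. Problem sizes

The bundled studies use 72 h traces at 0.5 Hz (~130 k samples,
~285 valence windows, ~4 100 one-minute windows), five generator seeds
for decoding comparisons and three seeds × 20 permutations for the
null. These sizes give fold-mean balanced accuracies stable to a few
percent across seeds while keeping the full acceptance recomputation in
the tens of seconds on one CPU.

## 8. Known limitations

* The generator's couplings are linear-filter couplings; real plant
  responses are nonlinear, history-dependent and species-specific.
* Labels inherit the chamber's confound structure: V and A are
  anti-correlated by construction whenever humidity tracks temperature
  strongly (corr(V, A) ≤ −1/3 for perfectly anti-coupled H), so binary
  tasks are never fully independent.
* One-step memory acuity of the reservoir is deliberately traded away
  by the slow leak (0.2); the capacity benchmark runs at leak 0.5.
* Watering/lid-removal events, sensor dropout and the 100 Hz raw
  bioelectric stream are not simulated; the IR filter is exercised by
  construction rather than by realistic failure patterns.
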