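# Methods

## Pipeline

The package implements window-level AF detection from RR-interval streams
as a linear chain: labeled RRI acquisition (synthetic generation or
annotation ingest) → sliding-window segmentation with majority labeling →
random train/test split → bidirectional-LSTM training → portable weight
export → single-precision inference → confusion-matrix metrics. Each stage
is usable on its own; the CLI mirrors the chain one subcommand per stage.

## Synthetic rhythm model

The generator emulates the two regimes the classifier must separate, not
the full physiology of a Holter recording.

* **Sinus rhythm**: order-1 autoregressive Gaussian around `mean_rr_nsr`
  with stationary standard deviation `sd_rr_nsr` and lag-1 autocorrelation
  `ar1_nsr`. The AR(1) term stands in for slow autonomic modulation
  (respiratory sinus arrhythmia and baroreflex variation) without modeling
  it explicitly.
* **AF**: independent gamma draws with mean `mean_rr_af` and coefficient of
  variation `cv_af`. Independence plus elevated dispersion is the
  "irregularly irregular" signature; the gamma shape keeps intervals
  positive and right-skewed, as observed RRI marginals are.

Both regimes are truncated to (0.2, 2.0) s — roughly 300 down to 30 bpm —
by rejection, which at the default parameters rejects a negligible fraction
and so preserves the configured means and CVs to well within the test
tolerances. Defaults: `mean_rr_nsr` 0.80 s, `sd_rr_nsr` 0.05 s, `ar1_nsr`
0.4, `mean_rr_af` 0.60 s, `cv_af` 0.20 — textbook resting values (sinus
≈ 75 bpm with ~50 ms variability; AF faster and several-fold more
dispersed). The configuration validator enforces `cv_af >
sd_rr_nsr/mean_rr_nsr`, making AF strictly more dispersed by construction.

Paroxysmal behaviour is scripted as an episode schedule of
`(rhythm, n_beats)` segments. One integer seed expands to per-segment
substreams keyed by `(seed, segment_index)`, so editing one schedule entry
never changes the draws of other segments. The shipped 80-interval
transition fixture (40 sinus, then 40 AF, pinned seed) is the worked
example used across tests and docs.

**What passing tests on this data do not show:** the generator has no
ectopic beats, no annotation noise, no motion artifacts, no gradual rate
drift, and its two classes are strongly separated in mean and dispersion.
Near-perfect synthetic accuracy demonstrates that the trainer, the export
path and the engine are correct and consistent — not that the model would
reach comparable numbers on real Holter data, where reported accuracies in
this family of methods sit near 98%.

## Windowing and labeling

Window length L = 40 intervals, step 1, threshold T = 20: a window is AF
iff at least T of its per-interval labels are AF, with a tie at exactly T
counting as AF ("20 or more"). "Beats" in the rule are counted as the L
per-interval labels, each interval inheriting the label of its terminating
beat — the interval only exists once its closing R-peak occurs, and this
makes the 40-slot window commensurate with the threshold of 20. Windows
never span record boundaries. With n intervals, `floor((n − L)/step) + 1`
windows result; 80 intervals give 41.

The native split shuffles windows uniformly (80/20 by default). Because
step-1 windows overlap by 39 intervals, this leaks near-duplicates across
the split and inflates test scores; the implementation reproduces the
protocol as the default but logs a warning and offers `mode="record"`,
which keeps whole records on one side, for honest generalization estimates.

## Ingest

R-peak annotations at a known sampling rate (250 Hz for the AF Holter
databases) are differenced and divided by the rate to give intervals in
seconds. Rhythm markers (`(AFIB`, `(N`, ...) form a step function over
sample positions; each beat takes the code in force at its sample, and
`(AFIB` alone maps to AF by default (atrial flutter `(AFL` counts as
non-AF; the code set is configurable). Sample indices are 0-based
internally; user-facing window/interval positions are 1-based. The reader
consumes the rdann-style text export of PhysioNet annotations plus the
package's own two-column CSV dialect; no ECG filtering, ectopy rejection or
R-peak detection is performed — expert annotations are assumed upstream.

## Model and training

Topology as in the README: two full-sequence LSTM directions of 40 units
(gate order input | forget | candidate | output; sigmoid gates, tanh
candidate and output squashing), concatenation to 40 × 80, global max
pooling over time, dense ReLU of 50, dropout, dense sigmoid of 1. Closed
forms for the per-layer parameter counts — `4(U(F+U)+U)` per direction,
`fan_in·units + units` per dense layer — are asserted against the sizes of
the actually allocated tensors.

The trainer is pure numpy. Design choices where the protocol was open:

* **Loss** is binary cross-entropy on the logits (numerically stable
  softplus form); the single sigmoid output admits no other form.
* **Optimizer** Adam with lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-7; batch 128.
* **Initialization**: Glorot-uniform input and dense kernels, orthogonal
  recurrent kernels per gate block (QR with sign fixing for determinism),
  zero biases with the forget-gate block at 1.
* **Regularization**: inverted dropout at rate 0.5 on the dense ReLU
  activations; early stopping on validation loss with patience 10 and
  best-weight restoration; validation fraction 0.1 split off the training
  windows. Defaults cap at 200 epochs; the synthetic corpora used in tests
  and the acceptance script converge in a handful of epochs, so those runs
  cap at 15 with patience 5.
* **Inputs** are raw interval values in seconds. A per-corpus
  standardization switch exists (off by default); when on, the mean and
  standard deviation are baked into the weight bundle so every consumer
  applies the identical transform.
* **Decision threshold** 0.5 on the probability, with "≥" winning ties.

Backpropagation through time is hand-derived and checked against a
central-difference oracle (relative tolerance 1e-3 at ε = 1e-6) in the test
suite. All randomness — initialization, the validation split, batch
shuffling, dropout masks — flows from explicit integer seeds, so a rerun
with identical data and seeds reproduces the final weights bit for bit.
Training runs in float64 for gradient fidelity; the exported bundle is
float32.

## Portable bundle and inference engine

The bundle serializes the 10 tensors (2 directions × 3, 2 dense × 2) in a
fixed manifest order as a flat little-endian float32 blob plus a JSON
manifest recording the topology, gate order, per-tensor shapes, byte
offsets and CRC-32 checksums — a layout a firmware build can embed
directly. Loading re-verifies shapes and checksums and refuses corrupt
bundles.

The engine re-implements inference as an explicit per-window, per-time-step
recurrence in float32 — the arithmetic of a single-precision embedded FPU —
sharing no code with the vectorized trainer. The backward direction
consumes the reversed window and its outputs are re-reversed before
concatenation, giving full bidirectional context at every pooled step.
Parity tolerance is 1e-5 maximum absolute probability difference: wide
enough to absorb accumulation-order differences between the batched and
sequential routes (measured gaps are ~1e-7), far too tight to mask a
layout, gate-order or precision error. Thresholded labels are additionally
required to agree exactly wherever the reference probability is more than
1e-4 from 0.5.

## Metrics

Exact rational formulas on TP/FN/FP/TN with AF positive. A zero denominator
yields an explicit *undefined* (None plus a warning), never a silent 0 or
1, so aggregate reports cannot be corrupted by degenerate slices.
Percentages render at two decimals with half-up rounding. Structural
identities (accuracy as the prevalence-weighted mix of sensitivity and
specificity; F1 bounded by precision and sensitivity; class-swap symmetry)
are property-tested against exact `Fraction` arithmetic.

## Numerical and degenerate-input choices

* Intervals outside (0.2, 2.0) s are invalid on construction; generated
  intervals are kept inside by rejection.
* A sequence shorter than one window raises an explicit error rather than
  returning an empty set; a single-beat record cannot define an interval
  and raises an empty-input error.
* Max pooling breaks ties by the earliest time step (argmax convention);
  gradients route to that step only. Ties have measure zero under both the
  generator and real data.
* A single-class training set is a degenerate-data error, not a silent fit.
* Split sizes use the floor of the training fraction, clamped so neither
  side is empty.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
desk scale: 4,000 windows (2,000 per class, built by step-1 windowing of
two long single-rhythm records) for the end-to-end training check, 1,000
random configurations for the windowing oracle, and 5 weight draws × 1,000
windows for engine parity. These sizes make the full suite complete in a
few minutes on one CPU while keeping every statistical tolerance
comfortably powered. Corpus-scale quantities from the million-window Holter
databases (and anything hardware-bound: inference latency, power, energy)
are out of scope; the external long-term database is reachable through the
generic ingest path but is not exercised by the tests.

## Known limitations

* The generator's two-regime model omits ectopy, artifacts and borderline
  rhythms (e.g. atrial flutter), so synthetic performance ceilings are
  optimistic.
* The window-level split is leakage-prone by construction; record-level
  splitting is provided but is not the default protocol.
* The engine is single-window and unoptimized by design — it is a
  correctness reference for deployment, not a fast batch scorer.
* Only the rdann text form of PhysioNet annotations is parsed; binary
  annotation files must be exported to text first.
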