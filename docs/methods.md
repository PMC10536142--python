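# Methods

This note documents the models and procedures implemented in `rehabband`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic experiments show.

## Sensor calibration

Thin-film force-sensitive resistors read through a Wheatstone bridge and a
12-bit ADC yield dimensionless AD counts whose relation to applied force
(gram-force, gf) is nonlinear and path dependent. Loading and unloading
sweeps are fitted separately with continuous piecewise-linear functions of
the AD count, and prediction averages the two fits, splitting the
hysteresis band.

Given interior breakpoints t₁..t₍ₘ₋₁₎ the fit is ordinary least squares in
the hinge basis f(x) = β₀ + β₁x + Σ cₘ·max(0, x − tₘ), which is continuous
by construction. The breakpoints themselves are chosen by minimizing the
residual sum of squares: a deterministic start at data quantiles, a seeded
differential-evolution search (bounds = data range, popsize 20, up to 250
generations), and a Nelder–Mead polish. A candidate replaces the incumbent
only when it strictly lowers the RSS, so data that the quantile solution
already fits exactly (e.g. collinear points) keeps the deterministic
breakpoints. On noise-free data generated from a piecewise-linear function
with as many segments, the fit recovers the generator to ~1e-13 gf at the
sampled points (asserted at 1e-4 in tests to leave optimizer slack).

Parameters: `n_segments` (default 9, the segment count used for the
physical sensor; exposed because nothing in this package endorses 9 as
optimal), `seed` (recorded in the serialized curve). Predictions outside
the calibrated AD range linearly extrapolate the terminal segments, with a
logged warning — clamping would introduce a spurious flat region.
Calibration error is reported signed, f_error = f_predict − f_true, with
percent error flagged undefined at f_true = 0 (the reference gauge has a
dead zone near zero force).

## Normalization and feature layout

Raw windows are 3×30 matrices of AD counts (three channels — palmar,
radial, dorsal — 30 samples at 15 Hz ≈ one complete action within 2 s).
A session binds per-channel references Ref_i, the mean of a 30-sample
resting recording; all windows are divided elementwise by Ref_i. The
ratios are dimensionless and make thresholds and classifiers invariant to
band tightness and amplifier gain (normalization is exactly invariant to a
common gain applied to raw data and reference). The classifier input is
the window flattened channel-interleaved, x(k) = u_α(β) with
α = ((k−1) mod 3) + 1 and β = ⌈k/3⌉; the ceiling convention is forced by
the requirement β ∈ 1..30 for k ∈ 1..90. One reference is bound per
(subject, round); rebinding is the caller's choice.

## Pre-detection gate

Two rules on the normalized sliding window (size 30, step 1):

- **peak rule**: max over channels of (max − min) over the oldest 10
  samples > T₁. A complete action must have its onset activity already in
  the oldest third of the window; quiescent windows fail.
- **head-tail rule**: min over channels of |first − last| < T₂. All four
  exercises start and end at the same posture, so a complete action's
  window is level end-to-end; the monotone ramps produced by switching
  initial postures between different exercises fail on every channel.

Defaults, in ratio units: **T₁ = 0.08**, **T₂ = 0.03**. Both thresholds
are empirical by nature; these values are calibrated against the noise
model rather than tuned to outcomes. With generator noise σ = 0.01 the
10-sample prefix range of a quiescent channel is below 8σ = 0.08 except
with negligible probability, while every action template rises by ≥ 0.19
within its first ten samples even at the worst amplitude draw — roughly a
3× margin on each side. (At T₁ = 5σ a quiescent window would false-fire
with per-window probability near a percent, which is too often for streams
thousands of samples long.) T₂ = 0.03 is ~3σ on a single-channel head–tail
difference: complete actions pass through the settled channel, ramps of
any practical posture change (≥ 0.1) fail on all channels.

After an accepted detection further detections are suppressed for
`refractory` = 30 samples (one window length), so one physical action
emits one event. Decisions depend only on window contents and thresholds.

### Classification alignment delay

The head–tail rule opens the gate at the first window whose every channel
has settled — systematically 2–6 samples before the window that frames the
action the way training windows do. Classifying that first window pushes
the action outside the timing-jitter range seen in training and measurably
costs accuracy (6/200 streaming label errors vs 0/200 with centering, on
the default generator). The detector therefore slides `classify_delay` = 3
further samples after the gate opens before classifying (the final window
if the stream ends first); the refractory countdown starts at
classification. The delay adds 200 ms of latency at 15 Hz, immaterial for
rehabilitation feedback. Setting `classify_delay = 0` restores
classify-at-first-acceptance.

## Autoencoder

Encoder 90 → hidden (tanh) → code (linear); the decoder is the
mirror-symmetric completion code → hidden (tanh) → 90 (linear) with untied
weights — the minimal architecture consistent with an encoder-only
specification. Defaults: hidden 40, code 10, Adam (step 1e-3), MSE loss,
minibatch 200 (a single full batch when the training set is smaller), 500
epochs, 8:2 train/validation split at the sample level (a per-subject
split is the caller's option via pre-splitting). Weights initialize from a
seeded symmetric uniform fan-in distribution U(±1/√fan_in); biases start
at zero. One integer seed controls split, init and batch order, giving
bitwise-reproducible histories and weights. A configuration with
code ≥ hidden warns (the bottleneck is then wider than the hidden layer
and such points train poorly — visible as the non-converging corner of the
hyperparameter grid). Models serialize to JSON with row-major weight
arrays so the forward pass can be re-implemented on a microcontroller from
the file alone.

## Pairwise SVM voting

Six soft-margin linear SVMs (C = 1, tolerance 1e-4, unweighted classes;
fitted by scikit-learn's SVC with a linear kernel), one per unordered pair
of the four actions, each trained only on its two classes' codes. Each
member votes by the sign of its decision value; a value of exactly zero
votes for the lower class index (a measure-zero case fixed for
determinism). Tallies over the six members always sum to 6, the maximum
attainable tally is 3, and a class that wins its three pairwise contests
necessarily wins the vote (verified by exhaustive enumeration of all 64
sign patterns). Ties among equal tallies break by the greatest sum of
signed decision values over the members involving the tied class — using
the available margin information — with the lowest class index as the
deterministic final fallback.

## Model selection and metrics

- **Grid search**: stratified seeded 10-fold CV over (hidden, code). Per
  grid point it reports (a) mean autoencoder validation MSE across folds
  and (b) the pipeline error rate computed with the encoder trained once
  on *all* samples and only the SVM ensemble cross-validated on the codes.
  Protocol (b) leaks the held-out fold into the encoder; it is kept as the
  primary protocol because it is the stated evaluation procedure this
  package reproduces, and a `leakage_free=True` variant re-trains the
  encoder inside every fold for comparison.
- **Generalized k-fold separability**: both classes are shuffled (seeded)
  and split into k subsets; fold i trains a linear SVM on the *pair*
  (A_i, B_i) alone and tests on all remaining samples, pairing subsets by
  index. The mean of the k misclassification rates quantifies linear
  separability: ~0 for well-separated sets, ~0.5 for identical
  distributions. Training on the small subset and testing on the large
  remainder is what distinguishes this from ordinary CV and makes the
  index sensitive to class overlap rather than to classifier capacity.
- **Metrics**: per-class P = TP/(TP+FP)·100 and R = TP/(TP+FN)·100 from a
  4×4 confusion matrix with an optional fifth "not recognized" column
  (those windows count as FN of the true class but as no one's FP).
  Aggregate P and R are unweighted macro means over the four actions —
  the only averaging consistent with the reported device totals — and the
  aggregate f1 is the harmonic mean of the two aggregates. Zero
  denominators flag the class as undefined rather than silently zeroing.

## Synthetic generator

The generator emulates the *structure* the pipeline assumes, not patient
physiology: per-subject resting baselines drawn uniformly from 800–1600 AD
counts (mid-range of a 12-bit ADC), a per-subject amplitude scale
U(0.85, 1.15), and four action templates built from raised-sine bumps with
distinct channel-weight signatures (double bumps on all channels for the
two-phase fist exercise; radial/dorsal-dominant bumps for finger
separation; sequential palmar-then-dorsal bumps for flexion/dorsiflexion;
one radial-dominant asymmetric bump for ulnar deviation). Per sample:
amplitude jitter ±20%, integer timing jitter ±2 samples, additive Gaussian
noise σ = 0.01 ratio units. Sessions concatenate rest segments, actions
and linear posture-switch ramps at 15 Hz with ground-truth onsets.
Calibration sweeps sample user-supplied generating curves on monotone AD
grids with optional force noise. Everything is bit-reproducible under a
seed.

Two template properties are enforced by construction and verified by
test: every template starts and ends within T₂ of baseline with onset
activity exceeding T₁ inside the oldest prefix (so complete actions pass
the gate), and every channel carries terminal activity ending near sample
28. The second property is what lets the head–tail rule certify
*completeness*: with a channel that settles early, a window missing the
action's tail still shows one near-zero head–tail distance, passes the
gate, and can fire twice per action. Real exercises plausibly share this
property (all three wrist sites stay loaded until the hand returns to the
initial posture), but it is a modelling assumption, not data.

What passing tests therefore show: the pipeline recovers the generating
labels of a process with the assumed structure (distinct smooth channel
signatures, modest jitter, Gaussian noise, stable baselines) at
macro-F1 = 100% for 5 unseen synthetic subjects. What they do not show:
performance on physical sensors, whose inter-subject variability,
drift, motion artefacts and hysteresis-under-partial-unloading are outside
the generator; the ~89% device-level scores are not reproducible at a
desk and are not claimed here.

## Problem sizes and numerical choices

The test suite and acceptance script use: 5 training + 5 unseen subjects ×
50 reps × 4 actions (1000 windows each side) for recognition; 20-action
sessions for streaming; 300-point sweeps and 4-segment generators for
calibration (9-segment fits exercise the same code path more slowly); a
reduced hyperparameter grid {10, 40, 60} × {5, 10, 25} with 10-fold CV,
120 epochs and 200 samples for the validation-error trend. These sizes
keep the full suite around half a minute while leaving every measured
margin wide (the F1 criterion passes at 100 vs the 95 threshold; the gate
rates are exactly 100/0 over hundreds of windows).

Numerical details worth knowing: degenerate calibration inputs (zero AD
range, too few points per segment) raise typed errors rather than fitting;
optimizer-collapsed breakpoints are nudged apart by a relative 1e-9 guard;
the autoencoder records full-pass train/validation MSE once per epoch;
SVC fitting is deterministic for fixed data, so end-to-end determinism
holds through the sklearn boundary.

## Known limitations

- Thresholds T₁/T₂ are calibrated to the generator's noise model; a
  physical deployment would re-derive them from resting recordings.
- The gate admits windows missing at most ~3 tail samples (the raised-sine
  taper is below T₂ there); the classification delay re-centers these, but
  a pathological action with a long sub-threshold tail could still be
  clipped.
- One reference per (subject, round) assumes the band is not re-tightened
  mid-round; drift within a round is not modelled or corrected.
- The grid's pipeline error rate inherits the single-encoder leakage of
  the stated protocol unless `leakage_free=True` is requested.
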