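# Methods

## Data model

A recording is one participant's two-foot stream at a common sampling rate
(100 Hz throughout): per foot, 8 plantar-pressure channels quantized to
levels {0, 1, 2} and 3+3 accelerometer/gyroscope channels as integers in
[−32768, 32768]. Feet are stored and segmented independently; the two feet
of one recording may differ in length. On disk a recording is a pair of
CSV files (`time,p1..p8,ax,ay,az,gx,gy,gz`) referenced by a manifest CSV —
text formats keep fixtures inspectable and round-trip value-exactly.

## Walking-cycle segmentation

The mean of the eight pressure channels is convolved with a sampled
Gaussian kernel of standard deviation σ (default 0.2 s), truncated at ±4σ
(±0.8 s = 81 samples at 100 Hz) and renormalized to unit sum; the
truncation error is below 1e−4. Ends are zero-padded: swing-phase pressure
is ~0, so zero is the natural extension. Cycle boundaries are the discrete
local minima of the smoothed signal. On sampled data the continuous
condition (first derivative zero, second positive) is ambiguous, so the
discrete rule is `z[i−1] > z[i] <= z[i+1]`; a flat plateau contributes its
first index. Minima closer together than `min_sep_s` (default 0.4 s,
comfortably below any human step period) are thinned deepest-first, ties
to the earlier index — this removes jitter minima produced by smoothed
noise bumps without biasing boundary positions. Each consecutive boundary
pair [tᵢ, tᵢ₊₁) yields one unit step; samples before the first and after
the last boundary are discarded.

The naive alternative — declare a boundary wherever the mean pressure
rises from zero — is kept (`naive_boundaries`) as the baseline that
spurious swing-phase pressure defeats; on 5%-spur synthetic cohorts it
produces roughly 3× the true step count while the smoothed-minimum rule
recovers ~99% of boundaries within ±0.1 s.

## Standardization

The standard length d is the minimum realized step length across both
feet of all participants (87 in the cohort this package models; 43 is a
supported variant for shorter-sequence recurrent models), and all steps
are resampled to d points evenly spaced over [0, len−1] with a cubic
spline (natural end conditions; steps shorter than 4 samples fall back to
linear, since a cubic needs 4 knots). Cubic splines reproduce affine data
exactly and preserve endpoints, which the tests exploit as oracles.

Feet are then concatenated per modality. The pairing of left to right
steps is by detection index within a recording (i-th left with i-th
right), with trailing unmatched steps dropped — the simplest consistent
rule; a time-overlap pairing would differ only when a detector misses a
step on one foot. Grouping k consecutive steps (k ≤ 4) stacks rows per
participant in temporal order, non-overlapping, discarding a trailing
remainder, so a participant with n steps yields ⌊n/k⌋ samples.

Before modelling, pressure is divided by 2 (→ [0, 1]) and IMU channels by
32768 (→ [−1, 1]); raw ±32768 integers destabilize training.

## Networks

Both classifiers share the branch-plus-head layout; branches are
per-modality and identical in form across modalities.

- CNN branch: three 1-D convolutions over time with 32, 64, 128 filters,
  kernel length 20 spanning all input channels, stride 1, zero 'same'
  padding (time dimension k·d preserved), each followed by ReLU; the last
  feature map is flattened. No pooling anywhere.
- LSTM branch: two layers of 64 units with hard-sigmoid gate activations
  (clip(0.2x + 0.5, 0, 1)) and tanh cell/output activations; recurrent
  dropout 0.2 applied as one mask, fixed across time steps, on the hidden
  state entering the recurrent matmul; forget-gate bias initialized to 1.
  Layer 1 returns its (k·d)×64 sequence, layer 2 its final 64-vector.
- Head: dense 256 + ReLU → dropout with keep probability 0.7 (training
  only) → dense softmax over participants.

The ensemble prediction is the elementwise mean of the two softmax
vectors; it is computed from stored branch outputs, never re-inferred, so
branch and ensemble accuracies always refer to the same forward passes.

The engine is pure NumPy (float32, im2col convolutions, full
backpropagation through time). Training: softmax cross-entropy, Adam at
learning rate 1e−3 with global-norm gradient clipping at 5, batch size 32,
up to 50 epochs with early stopping on a training-loss plateau (patience
3, min-delta 1e−3) or saturated training accuracy. These training choices
are this package's own; the architecture fixes everything else. All
randomness (init, shuffling, dropout) derives from the config seed, so
training is bit-reproducible.

## Evaluation protocols

Splits are stratified per participant — every class appears in train and
test, otherwise training is undefined. Test totals are round(0.3·N) for
MCCV(30%) and ⌊N/2⌋ for MCCV(50%), allocated across participants by
largest remainder within [1, nⱼ−1]; Sub-MCCV(50%) takes 2·⌊0.42·nⱼ⌋
samples per participant and splits them evenly, using ~84% of the cohort
in total. The default is 20 repeats with full retraining per repeat;
experiment runs derive per-repeat split and model seeds from one master
seed. t-SNE embeddings of the 256-unit head activations use
scikit-learn's implementation.

## Synthetic cohorts

The generator emulates what the pipeline assumes rather than human
biomechanics. Per participant it draws: step period mean ~ U(0.95, 1.25) s
with cycle-to-cycle s.d. ~ U(0.02, 0.05) s (≈160 steps per foot in 3 min,
the scale of the motivating acquisition); stance fraction U(0.55, 0.70);
per-sensor firing windows inside stance (onsets staggered heel-to-toe,
offsets mirrored, ±0.08 jitter) with a per-cycle level draw from {1, 2};
six IMU channels as 3-harmonic cycle-locked sinusoid mixtures (amplitudes
U(1500, 9000), decaying per harmonic; phases U(0, 2π)) plus white noise
with s.d. U(100, 300), quantized and clipped to the sensor range. Feet
walk in anti-phase. The spurious swing-pressure artifact is modelled as
independent per-sample level-1 blips on one random sensor at probability
`spur_rate` (default 0.02).

Two generator conventions matter for validation. Ground-truth boundaries
are defined at mid-swing — the center of the zero-pressure gap — because
that is where the smoothed-minimum detector's boundary concept lives; a
heel-strike truth would differ from any minimum-based detector by a
constant phase offset and make localization error unmeasurable. And the
mirrored onset/offset stagger makes the aggregate pressure hump symmetric
about the stance center, so the smoothed minimum is an unbiased estimate
of mid-swing; with asymmetric patterns the minimum shifts by a
participant-specific constant (tens of ms). One boundary is generated
before t=0 and one after the end so the recording starts and ends
mid-gait, as a real capture does; only boundaries ≥0.15 s from the edges
are reported as truth.

What the generator does not emulate: ground-reaction-force curve shapes,
double support, sensor drift, session-to-session variability, or
footwear/surface effects. Synthetic gaits are more separable than real
ones — participants differ in cadence, firing pattern and IMU harmonics
simultaneously — so near-perfect synthetic identification accuracy
validates the pipeline's mechanics, not field-grade biometric performance.

## Problem sizes

The reference experiment (`scripts/acceptance.py`, also run as an
acceptance test) uses 10 participants at ~165 s each (~150 steps per
foot, ~1500 paired unit steps, realized d near 87), one MCCV(30%) split,
and an epoch budget of 12 with early stopping — about three minutes on one
CPU, and comfortably past the 99% ensemble-accuracy mark. Unit tests use
smaller cohorts (2–5 participants, 30–60 s).

## Known limitations

- The LSTM applies one recurrent-dropout mask per sequence rather than
  per-gate masks; the regularization strength differs slightly from
  framework implementations.
- Sub-MCCV's per-participant allocation is one of several rules
  consistent with "equal halves from ~84% of the data"; totals, not the
  exact draw, are contract-tested.
- Index-based foot pairing assumes both feet yield the same step count;
  detector misses desynchronize the pairing for the remainder of a
  recording (bounded by dropping trailing steps).
- Training hyperparameters are fixed, not searched; accuracy on real
  (non-synthetic) data would need its own tuning and validation.
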