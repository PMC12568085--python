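# Methods

`eyewrite` classifies *eye-writing*: character-shaped patterns traced with
eye movements, recorded either as EOG signals or as gaze coordinates from
a camera. A recording is a variable-length sequence of (x, y) samples; the
task is to recognise which of C patterns was written, and to do so for
users the model has never seen (user-independent evaluation).

This note documents the model, its assumptions, the tunable parameters,
the synthetic data the package is tested on, and the numerical choices
made where the design was genuinely open.

## Preprocessing

### Signal conditioning (EOG-style recordings only)

Three per-channel stages, in order:

1. **Median filter** (window 5 samples). Removes 1–2-sample spike
   artifacts (blinks, electrode pops) without rounding stroke corners at
   64–125 Hz sampling. The window size is a package choice; it is the
   smallest odd window that spans a two-sample spike.
2. **Zero-phase Butterworth low-pass** (order 5, cutoff 10 Hz). Writing
   strokes live well below 10 Hz; everything above is sensor noise. The
   filter is applied forward–backward (`scipy.signal.filtfilt`), so the
   trajectory geometry suffers no phase lag, at the cost of −6 dB rather
   than −3 dB at the cutoff (half amplitude exactly at 10 Hz — asserted in
   tests). The Butterworth family is the conventional EOG choice and is
   what an order/cutoff parameterisation implies.
3. **DC blocker**, the first-order IIR recursion
   `y[n] = x[n] − x[n−1] + p·y[n−1]` with pole p = 0.995. Removes the
   constant offset of the corneo-retinal potential. A recursion rather
   than batch mean-subtraction because a "filter" should be streamable; a
   constant offset decays geometrically with ratio p.

Webcam-style gaze data skips all three stages: the capture path already
yields clean, offset-free coordinates.

### Fourier-domain length normalization

Recordings span roughly 1.7–24 s, so lengths vary by an order of
magnitude, while the network wants a fixed input length M (default 64).
Per channel, with L the input length:

1. forward DFT `X(k) = Σ_n x(n) e^{−j2πkn/L}`;
2. if L > M, keep the M lowest-frequency bins in standard DFT order —
   `Xd(k) = X(k)` for `k < ⌈M/2⌉`, `Xd(k) = X(k+L−M)` otherwise; if
   L < M, zero-pad symmetrically in the same bin convention (the two maps
   are exact inverses of each other);
3. inverse DFT of length M (1/M convention), real part, times M/L.

Truncation simultaneously resamples and denoises: the written shape lives
in the lowest handful of bins, and high-frequency jitter is simply
dropped. Two conventions deliberately exposed as options:

- **Truncation indexing** (`truncation_convention`): the default
  `lowpass` keeps low frequencies of the standard-order spectrum; the
  alternative `centered_literal` selects a centred block
  `X[(k+⌈(L−M)/2⌉) mod L]`, which is the natural reading only if the
  spectrum were in zero-centred order. The default is the one that
  actually removes high frequencies and inverts the padding map.
- **Amplitude** (`amplitude_mode`): the bare 1/M inverse scales amplitude
  by L/M, making it depend on how long the user took to write. The
  default `preserve` multiplies by M/L so a constant channel maps to the
  same constant for any L; `literal` keeps the bare convention.

Even target lengths carry a caveat: the bin retained at the new Nyquist
position keeps its complex value (no conjugate partner), so the inverse
transform of a real signal acquires a small imaginary residue, removed by
taking the real part. For odd M, or any signal with no content at the
split bin, the residue is zero to rounding error (both asserted in
tests).

### Initial-point normalization

`p'_i = p_i − p_0`: the trajectory is translated so it starts at the
origin, removing absolute-position variability between users and trials.
Applied after length normalization, because the spectral resampling moves
the first sample.

### Zero-padding baseline

For ablation comparisons the spectral and initial-point steps can be
replaced by appending (0, 0) points up to a fixed length, never
truncating. On the synthetic webcam-style data the pad length is 720
samples (the longest possible recording, 23.51 s × 30 Hz = 705, rounded
up to a multiple of 4 for the pooling stack).

## Augmentation

Applied to raw training trajectories only — augmented copies carry a
provenance tag and split construction refuses them in test folds.

- **Segmental distortion**: at boundaries i = 0, g, 2g, … (< N), fresh
  per-axis factors `s_x, s_y ~ N(μ, σ²)` multiply every coordinate from
  the boundary onward, so factors compound along the sequence. Two preset
  variants: I (μ=1.0, σ²=0.1) and II (μ=1.01, σ²=0.01); gap g = 32
  samples (64 for the 64 Hz EOG-style configuration). Negative draws
  (possible under variant I) are clipped to 0.01 — a negative scale would
  mirror the pattern, which "controlled distortion" excludes. A
  `per_segment` mode, in which each factor pair applies only within its
  own segment, is exposed for comparison; compounding is the default.
- **Window warping**: a contiguous window of ⌈N·r⌉ samples (r = 0.3) at a
  uniform-random start is linearly interpolated to ⌈N·r·s⌉ samples with s
  drawn from {0.25, 4.0}, stitched back between the untouched flanks, and
  the whole sequence linearly rescaled to length N. Emulates local speed
  changes.

Each original contributes exactly one copy per technique (three named
techniques → 4× training volume). Per-sample RNG streams are derived by
hashing (subject, label, trial, technique) with the master seed, so the
augmented set is independent of processing order.

## Model

Input: (B, L, 2), L = 64 by default. Two parallel branches:

- **1D CNN branch** — Conv(2→16, k=5, same padding) → ReLU →
  MaxPool(k=3, s=2, p=1) → Conv(16→32, k=5) → BatchNorm → ReLU → MaxPool;
  temporal length L → L/4. Local stroke-shape features.
- **TCN branch** — three residual blocks with dilations 1, 2, 4. Each
  block is two stages of [depthwise dilated causal conv (k=3) → pointwise
  1×1 conv → BatchNorm → ELU → Dropout(0.3)] plus a 1×1-projected
  residual skip; blocks 1–2 end in a stride-2 max-pool so the branch also
  lands at L/4; a squeeze-and-excitation gate (reduction 4) rescales the
  32 output channels. The depthwise–pointwise factorisation costs
  C·k + C·C′ weights against C·C′·k for a standard convolution (1120 vs
  3072 at 32→32, k=3).

Branch outputs are concatenated (64 channels × L/4), batch-normalised,
dropped out (0.3), flattened, and mapped to C logits by one linear layer.
`fusion` also offers `serial` (CNN output feeds the TCN), `cnn_only` and
`tcn_only` for ablations.

Design points that were genuinely open, and the choices made:

- **Pooling stride**: a k=3, stride-1, padding-1 max-pool preserves
  length and cannot "reduce temporal resolution"; the default is
  stride 2, honouring the stated purpose, with `pool_stride: 1`
  available to reproduce the length-preserving literal reading.
- **Branch alignment**: parallel fusion needs equal temporal lengths;
  pooling blocks 1–2 of the TCN (not block 3) matches the CNN's two
  pools.
- **Residual skips**: retained from the standard TCN design (1×1
  projection, pooled alongside the main path), since only the
  convolution type is replaced.
- **SE placement**: one gate on the TCN branch output; bottleneck ratio
  4, two linear layers (the canonical squeeze-excitation shape).
- **Causality**: the depthwise convs pad on the past side only, so
  pre-pool activations at time t depend only on inputs ≤ t (perturbation
  test in the suite). The centred pooling windows look one sample ahead,
  which is why causality is asserted on the pre-pool maps.
- Weight initialisation: fan-in uniform with a config seed, so every fold
  is reproducible.

The network and its training loop are implemented directly in numpy with
hand-derived backpropagation; every layer's gradient is verified against
central finite differences in the test suite. Training arrays are cast to
single precision, which halves step time with no measurable effect on
results (float32 vs float64 logits agree to ~1e-3).

## Training and evaluation

Cross-entropy loss `L = −(1/N) Σ_i Σ_j y_ij log ŷ_ij` minimised by Adam
with AMSGrad, L2 weight decay 0.1 (classical formulation, added to the
gradient — deliberately kept at its reference value despite being
unusually large), and
a cosine-annealing warm-restart schedule: maximum learning rate 1e-3,
period 16 epochs, minimum 0 (1e-6 for the 64 Hz EOG-style
configuration). The reference recipe trains 400 epochs at batch 512; the
desk-scale runs in this package use 50 epochs at batch 64, which saturate
the synthetic benchmark.

Evaluation is leave-one-subject-out: one fold per subject, trained from
scratch on all other subjects (augmented + originals, all preprocessed),
scored on the held-out subject with final-epoch weights. No inner
validation split exists — with a held-out subject there is no principled
way to build one. Metrics are accuracy and macro-averaged precision,
recall and F1, reported in percent with mean and population standard
deviation across folds. Under balanced test classes macro recall equals
accuracy exactly, a useful cross-check. A class absent from the truths
enters the macro average only if it was (wrongly) predicted.

Configurations are compared with a two-tailed Wilcoxon signed-rank test
on paired per-subject accuracies: zero differences dropped, mid-ranks for
ties, exact enumeration of all 2^m sign assignments up to m = 20 (so a
6-subject design bottoms out at p = 2/2⁶ = 0.03125, a 5-subject one at
0.0625), tie-corrected normal approximation with continuity correction
beyond. All-zero differences give p = 1 by convention.

## Synthetic data

The generator emulates the structure the method assumes, not any real
corpus:

- 10 numeral-like or 12 Katakana-style single-stroke polylines in the
  unit square (package-defined geometry; one Katakana stroke is the
  left-up-right-down-left rectangle);
- per-subject affine style: offset ~ N(0, 0.15²), axis scale ~ N(1,
  0.10²), drawn once per subject;
- per-segment speed jitter (uniform ±30%), with grid instants snapped to
  vertex times so noiseless traces hit corners exactly;
- duration ~ Uniform(1.69 s, 23.51 s) at 30 Hz (webcam-style default) —
  sample lengths span ~51–705, exercising both the truncation and padding
  branches of the normalizer;
- Gaussian fixation noise (σ = 0.01 units) and, in the EOG-style
  configuration (125 Hz), sporadic unit-scale spikes for the median
  filter to remove.

What it does **not** model: saccade/fixation physiology (main-sequence
dynamics), blink waveforms, gaze-estimator bias fields, or any published
glyph geometry. Passing tests therefore demonstrate that the pipeline and
model behave as specified on data with the assumed statistical structure,
not that the published real-data accuracies are reproduced — those
require the external corpora and 400-epoch training.

## Problem sizes used in tests and the acceptance script

The end-to-end runs use 6 subjects × 10 patterns × 5 trials (300
recordings), 50 epochs at batch 64 — sizes chosen so a full
leave-one-subject-out evaluation completes in minutes on one CPU while
still training ~20k parameters on ~1000 augmented samples per fold. The
zero-pad-baseline comparison runs 5 seeded repeats at 5 epochs: the gap
between the spectral pipeline and the baseline (tens of percentage
points) is already unambiguous at that depth.

## Known limitations

- The synthetic benchmark saturates near 100%; it separates working from
  broken pipelines but cannot rank near-equivalent model variants the way
  the real corpora would.
- The numpy implementation is CPU-bound and single-threaded; it is built
  for correctness and desk-scale experiments, not large-scale training.
- Even-length spectral truncation is non-Hermitian at the split bin (see
  above); the real-part extraction makes this exact only for band-limited
  or odd-length cases.
- The exact Wilcoxon path enumerates 2^m assignments and is capped at
  m = 20 nonzero differences before switching to the normal
  approximation.
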