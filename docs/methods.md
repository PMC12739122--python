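# Methods

This note documents the modeling and engineering decisions behind
`beatfusion`: what the pipeline computes, which knobs matter, what the
synthetic data does and does not emulate, and where the design was genuinely
open.

## Problem setting

The package classifies individual heartbeats from a single ECG lead into
the five AAMI-style classes: N (normal and bundle-branch-block beats),
S (supraventricular ectopic), V (ventricular ectopic), F (fusion of
ventricular and normal), Q (unclassifiable/artifact). Beats are taken as
given — R-peak locations and beat symbols come from annotations, not from a
detector — and each beat is classified independently; rhythm-level context
across beats is out of scope.

## Preprocessing

- **Band-pass filter**: 4th-order Butterworth, 0.5–50 Hz, applied
  forward-backward (`sosfiltfilt`) for zero phase. The 0.5 Hz corner settles
  slowly, so the signal is padded with an even reflection of about three of
  that corner's time constants (`3·fs/low` samples) before filtering;
  otherwise edge transients of the high-pass pole leak far into the record.
  The filter is applied to the whole record before segmentation.
- **Segmentation**: half-open window `[r − ⌊w/2⌋, r + ⌈w/2⌉)` centered on
  the annotated R-peak, default w = 360 samples (one second at 360 Hz covers
  P through T at normal rates). Beats whose window crosses the record
  boundary are skipped and counted; non-beat annotation symbols (rhythm
  labels, signal-quality marks) are skipped and counted, so
  segments + skips always equals the number of annotations.
- **Normalization**: each beat is z-scored individually (sample sd,
  ddof = 1). Per-beat normalization is the more robust reading of
  "zero mean, unit variance" for heartbeat classification, since it removes
  per-beat gain and offset; a record-level alternative would preserve
  relative amplitudes across beats but couple beats to slow gain drift. Both
  the window length and the normalization scope are configurable.
- **Split**: stratified 70/10/20 train/validation/test with
  largest-remainder allocation per class, so each per-class split count is
  within one beat of `count × fraction`. A class with fewer than three beats
  is kept whole in train (with a warning).
- **Augmentation** (training split, minority classes only — every class but
  the most frequent): time stretch uniform in [0.9, 1.1] and amplitude scale
  uniform in [0.8, 1.2], redrawn every epoch. Stretching resamples linearly
  and center-crops/zero-pads back to the window.

## Architecture

- **CNN blocks**: valid (unpadded) convolution → ReLU → non-overlapping max
  pool (window 2) → dropout. Defaults: three blocks, channels 16→32→64,
  kernel 3, dropout 0.3. A residual shortcut runs alongside each block; a
  1×1 convolution is inserted in the shortcut only when the input and output
  channel counts differ. Because the main path's valid convolution shortens
  the sequence, the shortcut is center-cropped by ⌊K/2⌋ per side and pooled
  with the same window before the addition. Pooling is plain max pooling —
  no bias or activation is applied inside the pooling step; a biased,
  activated downsampling variant is nonstandard and is deliberately not
  offered. After the blocks, one fully connected layer maps the flattened
  features to a fixed (T × d_c) sequence (defaults T = 16, d_c = 64).
- **Transformer encoder**: defaults 4 layers, 4 heads, d_model = 256,
  d_k = d_v = 64, FFN width 512, dropout 0.1 — the 256-dimensional,
  4-head geometry; a 768-dimensional, 12-head geometry is available through
  the same config fields. Positional encodings are *learned* embeddings,
  one trainable vector per position. The [CLS] summary token is a learned
  vector prepended to the embedded sequence — the standard adaptation when
  the input is a feature sequence rather than text tokens. Layers are
  pre-LayerNorm (LN before each sublayer), which trains more stably at
  small scale than the post-LN arrangement; a final LayerNorm closes the
  stack. Padding positions are masked out of attention by a −1e30 logit
  fill, which underflows to exactly zero weight after softmax, and the
  padded steps are zeroed before the trailing convolution so they cannot
  leak inward through its receptive field. Masked-segment pretraining is
  not implemented: the model is trained supervised end to end.
- **Fusion**: the trailing convolution of the encoder and the CNN projection
  are configured to emit the same T, so no interpolation is needed. The
  cross attention is multi-head (d split into h contiguous blocks, default
  h = 1, in which case it reduces to the single-matrix form). The gate makes
  each fused element an exact convex combination of its two sources. The
  classifier mean-pools the fused sequence over valid steps and concatenates
  the [CLS] summary before the linear softmax layer; what the classification
  layer should consume is not otherwise pinned down, and pooling + summary
  concatenation keeps both local (fused) and global ([CLS]) information.
- **Initialization**: Kaiming-uniform for convolution and linear weights,
  zeros for biases, N(0, 0.02) for [CLS] and positional embeddings, all
  drawn from one seeded generator.

## Training

- **Focal loss**: γ = 2 by default; α is the inverse training-split class
  frequency normalized to mean 1, so the loss scale is comparable to
  uniform weighting. γ = 0 with uniform α is exactly cross-entropy (tested
  to 1e−12). p_t is clamped at 1e−12 with a logged warning; no infinities.
- **Schedule**: `lr = lr_max · min(step/warmup_steps, √(warmup_steps/step))`,
  1-based; both branches meet at lr_max when step = warmup_steps. Defaults:
  lr_max = 1e−3, warm-up fraction 0.08 of total steps (inside the customary
  5–10 % band), batch 64, max 50 epochs, patience 5. None of these are
  forced by the problem; they are engineering defaults exposed in the
  config.
- **Selection**: validation macro-F1, not accuracy — with an 84 %-N class
  mix, accuracy barely registers minority-class regressions, and the
  minority classes are the point of the exercise.
- **Early stopping**: the counter resets on strict improvement and training
  stops once it reaches `patience`; the best-validation weights are restored
  at the end and are what any checkpoint on disk contains.
- **Two-stage option**: `training.two_stage` freezes both encoders and
  trains only the fusion stage and head (the feature streams are detached
  from the graph). Default is end-to-end joint training, which is the
  simpler and better-conditioned choice at this scale; the flag exists
  because staged training is a plausible alternative reading of the design.
- **Determinism**: one `numpy` Generator seeded from `training.seed` drives
  initialization, shuffling, dropout and augmentation, and all arithmetic is
  float64, so a fixed seed reproduces the loss trace bit-for-bit on a given
  platform.

## Synthetic data

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) on the unit
interval plus per-beat timing jitter (sd 0.01 of the window, shifting all
waves together) and white Gaussian noise (sd 0.05, dimensionless mV-like
units). Class templates: N is a canonical P-QRS-T; S shifts the P wave 0.08
earlier (premature atrial activation); V triples the R width, deepens S and
inverts T, with no P wave (wide-QRS ventricular morphology); F is the
parameter-wise midpoint of N and V (fusion beat); Q redraws all five
amplitudes uniformly in [−0.5, 0.5] per beat (low-structure artifact). The
default class mix is N:S:V:F:Q ≈ 0.828 : 0.026 : 0.066 : 0.007 : 0.073
(weights normalized, counts allocated by largest remainder so the total is
exact), emulating the N-dominated imbalance of a real ambulatory beat
inventory.

What this emulates: class-distinct morphology at realistic SNR, beat
misalignment, and severe class imbalance — the failure modes the loss,
augmentation and metrics machinery exist for. What it does not emulate:
inter-beat rhythm context, baseline wander and electrode artifacts,
inter-patient morphology variability, multi-lead structure, or the
within-class diversity of real arrhythmias. A nearest-centroid classifier
already scores ≳ 94 % on these beats, so passing the end-to-end learning
checks demonstrates that the full pipeline optimizes and generalizes
correctly — not that the architecture would reach any particular accuracy
on clinical recordings.

## Test-time problem sizes

The learning checks run a reduced geometry chosen as the smallest
configuration that exercises every architectural path: channels 8→16,
T = 16, d_c = 32, d_model = 32, 2 layers, 2 heads, d_k = d_v = 16,
fusion d = 32, trained for 10 epochs on 2,000 synthetic beats (1,400 train /
200 validation / 400 test). The 32-beat memorization check uses an even
smaller 3-class geometry with dropout off, and its validation split is a
copy of the 32 training beats so that model selection and the final score
measure the same memorization property.

## Numerical choices

- All tensors are float64; tolerance-critical oracles (convolution,
  attention, metrics) agree with brute-force implementations to 1e−9/1e−6.
- Softmax subtracts the row maximum; masked logits are filled with −1e30
  before the subtraction, giving exactly zero weight after exponentiation.
- Max pooling pools a trailing partial window as-is (output length
  ⌈L/window⌉); its gradient routes to the argmax (first maximum on ties).
- Metric conventions: any zero-denominator metric is 0 and flagged;
  aggregates are unweighted macro means by default (support-weighted via a
  flag); per-class accuracy is a one-vs-rest quantity, consistent with the
  other per-class metrics.
- The fixture format stores beats as a plain-text header plus a `savetxt`
  matrix at 10 significant digits; CSV round-trips are tested at 1e−9
  relative tolerance.

## Known limitations

- The WFDB reader covers the MIT-BIH subset only: single-`.dat` records in
  formats 212 and 16, MIT-format annotations. Multi-file records, other
  signal formats, and extended annotation content (AUX strings are skipped,
  not surfaced) are unsupported.
- The autodiff engine implements exactly the operations this model needs;
  it is not a general framework (no broadcasting matmul beyond numpy's
  rules, no higher-order gradients).
- Training is plain batched CPU numpy; large-scale runs (hundreds of
  thousands of beats, full-size geometry) are possible but slow.
- The nine-class variant is reachable by supplying a larger class
  vocabulary and matching templates, but no default nine-class template set
  is shipped because no principled class definitions exist for it.
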