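# Methods

This note documents the model as implemented, the choices made where the
design was genuinely open, the synthetic data regime, and what the tests do
and do not establish. Nothing here states an empirical number that the test
suite or `scripts/acceptance.py` does not itself compute.

## Compute engine

The package carries its own reverse-mode automatic-differentiation engine
on numpy (`duoseg.nn`): a `Tensor` records the operations applied to it and
back-propagates through the recorded graph. Primitives are limited to what
the network needs — broadcast arithmetic, matmul, 2-D convolution
(column-gather + BLAS contraction; strided-slice scatter in the backward
pass), non-overlapping max pooling, bilinear upsampling (expressed as a
pair of interpolation matrices, so the backward pass is exactly the
transpose), batch/layer normalisation, softmax and the usual activations.
Every primitive's gradient is verified against central finite differences
in `tests/test_autodiff.py`. All computation is float32 by default;
gradient checks and oracle-equivalence tests cast to float64. There are no
stochastic layers, so a forward pass is bit-reproducible.

MAC accounting happens inside the two primitives that do dense
multiply–accumulate work (convolution: k²·C_in/g·C_out·H_out·W_out;
matmul: output size × contracted dimension), counted once per fused
multiply–add during a profiling forward pass. Normalisations, activations
and interpolation are not counted; the doubled figure (2 ops per MAC) is
reported alongside for comparison with the other convention.

## Encoder

A four-stage pyramid transformer in the PVTv2 style: overlapping patch
embedding (7×7 stride 4, then 3×3 stride 2), spatial-reduction
self-attention (keys/values computed on a token grid reduced by a strided
convolution with per-stage ratios 8/4/2/1), and a convolutional
feed-forward (fc → depthwise 3×3 → GELU → fc), with a layer norm closing
each stage. The `b2` configuration is channels (64, 128, 320, 512), depths
(3, 4, 6, 3), heads (1, 2, 5, 8), MLP ratios (8, 8, 4, 4); its parameter
count is checked against an independent per-layer weight-shape enumeration.
The fused key/value projection of the reference design is implemented as
two separate linear layers — mathematically and parametrically identical.

Grayscale inputs are replicated to three channels so externally supplied
3-channel pretrained weights remain loadable through a local-file hook;
default initialisation is truncated normal (linear layers) and fan-out
normal (convolutions), fully determined by the build seed. A `tiny`
variant — channels (16, 32, 64, 128), depth 1 per stage, MLP ratio 2 —
exists purely so the full network trains in minutes on one CPU core.

## Decoder design choices

Where the architecture left free parameters, the defaults are:

* **Softmax axis** of the context gates: the channel axis at each pixel.
  A spatial softmax would scale the residual term like 1/(HW) and
  extinguish it; the channel softmax makes each gate a convex per-pixel
  channel reweighting, giving the invariant x′ᵢ − xᵢ = xᵢ ⊙ gᵢ with
  Σ_channels gᵢ = 1.
* **Channel plan**: fused input and context keep C_y = C_r = C₂ channels
  (so the stride-8 gate projection is cheap); the U-block's internal
  convolutions run at M = C_r/2; the cascaded-fusion paths are reduced to
  F_f = 64 channels each; the aggregated guide h has C_h = 64 channels;
  the attention gate's intermediate width is C_h/2. All are config fields.
* **×4 upsampling** in the stride-8 fusion is two chained ×2
  upsample-conv blocks (one convolution per upsampling step); the
  stride-8→stride-4 paths of the cascaded fusion use single blocks with
  1×1 kernels.
* **Logit heads** are plain 1×1 convolutions with no BN/ReLU — a ReLU
  would forbid negative class evidence. Intermediate upsample-conv blocks
  keep Conv–BN–ReLU.
* **Attention gate**: both nonlinearities are sigmoids; the final gate is
  a single channel broadcast across the low-level feature's channels.
* **Channel attention** restores the input channel count with its second
  projection (required for the elementwise product to be defined); the
  reduction factor defaults to 16 and is configurable downward for narrow
  test models. A non-restoring output width can be configured for
  auditing, in which case the forward pass refuses the ill-defined
  product.
* **Gated + guide combination** before CBAM is channel concatenation plus
  a 1×1 projection, preserving both signals.
* **Branch combination at inference** sums probabilities, not logits:
  sigmoids keep each branch's evidence on a common [0, 1] scale and the
  sum is monotone per class.

## Objective

Supervision is channel-wise binary with an explicit background channel:
each class map gets BCE (probabilities clamped to [10⁻⁷, 1−10⁻⁷]) plus
soft Dice with smoothing 1.0, weighted 1:1; the joint objective adds the
same loss on the elementwise product of the two branch probabilities. The
product of probabilities is itself a probability map (high only where both
branches agree), which is what makes the third term meaningful; applying
it to logits would not be. Ablation flags drop either branch (the network
then returns a single logit map) or the multiplicative term (the logged
total is then exactly loss₁ + loss₂).

## Training

AdamW (β = 0.9/0.999, ε = 10⁻⁸) with decoupled weight decay; defaults
lr 3·10⁻⁴, weight decay 10⁻⁵, batch sizes 8 (train) / 1 (validation),
constant learning rate — no schedule is applied, and the step budget is an
explicit config field. One master seed derives named sub-seeds
(splitmix64, reduced below 2³¹) for weight init, shuffling, noise
injection and repeat runs, so a run is exactly reproducible from its
config. A NaN loss aborts with a diagnostic. The checkpoint kept is the
best-by-validation-Dice state; checkpoints are `.npz` files carrying
weights, configs, the seed and a content hash that is verified on load.
The config's learning rate is allowed to be 0 (a degenerate run that
provably leaves parameters untouched — used as a test).

## Synthetic phantoms

The generator emulates the *geometry* of the target anatomy, not MRI
physics. The cardiac motif is a bright disk (blood pool, mean intensity
0.85), a ring of muscle around it (0.45) and an adjacent crescent-shaped
chamber (0.65) on a 0.15 background; classes beyond three are elongated
curved bands (articulator-like). Defaults: 128×128 images, per-sample
intensity jitter σ = 0.03, Gaussian blur σ = 1 px, shapes spanning roughly
8–12 % of the image size — proportions chosen to resemble short-axis
cardiac slices while leaving every class ≥ 20 px. Regions are rasterized
in fixed priority order (earlier classes win), so labels are pairwise
disjoint like real organ annotations. Inference-time robustness noise is
zero-mean Gaussian at σ ∈ {0.05, 0.1, 0.2} on the normalized [0, 1]
intensity scale, clipped.

What phantoms do *not* contain: acquisition artifacts (off-resonance,
motion blur), intensity non-uniformity, anatomical variability or
ambiguous boundaries. Tests passing on phantoms therefore establish the
*mechanics* (shapes, gradients, convergence, metric plumbing), not
clinical-grade accuracy on real MRI.

## Evaluation conventions

Dice of two empty masks is 1; Hausdorff distances over boundary pixels
(border pixels count as boundary) are undefined for empty masks and carry
a not-applicable sentinel rather than 0. The 95th-percentile variant takes
the percentile of each directed distance distribution before the final
max, so HD95 ≤ HD. Class means are foreground-only, and a class absent
from both maps is excluded from every mean — this neither inflates nor
deflates scores for absent structures; evaluation reports state the
convention. Distances are in pixels unless a physical spacing is given.

## Problem sizes

Desk-scale checks use the tiny encoder: the learning check overfits 8
phantoms (128×128, 3 foreground classes) for 300 steps — about four
minutes on one CPU core — and its model is reused for the noise sweep;
oracle-equivalence checks run on ≤ 8×8 feature maps in float64, where
brute-force compositions (scipy correlations, per-pixel interpolation
loops) are exact to 10⁻⁶. Capacity accounting runs the full b2 model once
at 256×256.

## Known limitations

* Strictly 2-D: NIfTI volumes are consumed slice-wise; no volumetric
  surface distances.
* The decoder channel widths above are this implementation's defaults;
  published parameter/MAC totals for same-family architectures depend on
  exactly these unstated widths, so capacity figures are comparable only
  qualitatively (the encoder's count, whose configuration is fully
  specified, is reproduced exactly).
* No data augmentation, learning-rate schedule, class-frequency weighting
  or boundary losses; single-process CPU execution only.
* The convolution backward pass favours clarity over peak speed; training
  beyond desk scale is out of scope.
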