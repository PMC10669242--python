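# Methods

This note records the models implemented in `rckd`, the conventions and
defaults behind them, the design choices made where the architecture left
room, and what the synthetic-data experiments do and do not establish.

## CSAT architecture

CSAT follows the convolutions-low / attention-high layout of recent
lightweight hybrid networks. The default configuration:

| stage | resolution | blocks | width |
|---|---|---|---|
| stem | H/4 | two 3×3 stride-2 convolutions (3→16→32), each with channel LayerNorm + GELU | 32 |
| stage 1 | H/4 → H/8 | 2 SAT blocks, then 3×3 stride-2 downsample | 32 |
| stage 2 | H/8 → H/16 | 2 SAT blocks, then downsample | 48 |
| stage 3 | H/16 → H/32 | 6 SAT blocks + 2 Transformer blocks, then downsample | 96 |
| stage 4 | H/32 | 4 SAT blocks + 2 Transformer blocks | 176 |

Blocks run at the stage's *input* resolution and the stride-2 3×3
convolution (with channel LayerNorm) sits at the stage *end*, carrying the
channel change; stage 4 has no further downsampling. A single 4×4 stride-4
"patchify" stem is available as a configuration variant.

**SAT block.** `y = x + SAT(Conv1×1(GRN(Conv1×1(DWConv7×7(x)))))` with a
channel LayerNorm after the depthwise convolution, a 4× expansion in the
first 1×1 convolution, GELU, and GRN on the expanded map. GRN divides each
channel's spatial L2 norm by the cross-channel mean norm (ε = 1e−6 in the
denominator), multiplies the channel by that ratio times a learned `gamma`,
adds `beta`, and adds the input residually; both parameters start at zero,
so GRN is the identity at initialisation. The depthwise convolution carries
no bias (a normalisation follows); the pointwise convolutions do.

**SAT module** (129 parameters each; 14 modules → 1,806 total). Channel-wise
average- and max-pooling are concatenated (2 channels), adaptively
average-pooled to a fixed `pooled_size × pooled_size` grid (default 7×7),
abstracted by a bias-free 7×7 convolution to one channel, and
position-encoded by a bias-free depthwise 3×3 PEG added to the descriptor.
One linear layer (1 → 11, with bias) produces Q, K of dimension d = 5 and a
scalar V per token; single-head attention `softmax(QKᵀ/√d)·V` yields the
7×7 attention map, which is bilinearly upsampled and multiplied into the
feature map. No extra nonlinearity is applied to the upsampled map (a
sigmoid gate exists behind a flag, default off). Both SAT-module
convolutions use replicate (edge) padding on the descriptor grid: with zero
padding, border tokens of a spatially constant input would differ from
interior ones, breaking the symmetry that a constant input must yield a
constant attention map; replicate padding preserves it and keeps the PEG a
purely relative encoding. Padding choice affects no parameter or MAC count.

**Transformer blocks.** Standard pre-norm encoder over the flattened spatial
tokens: LayerNorm → 8-head self-attention (QKV and output projections
without bias) → residual; LayerNorm → MLP (with biases) → residual. MLP
hidden widths are 4× the width in stage 3 (384) and 5× in stage 4 (880).

**Head.** Global average pooling, a parameter-free normalisation of the
pooled vector (the residual stream carries no final affine norm; bounding
the logit scale this way costs nothing and prevents early saturation), one
linear layer, softmax. The segmentation head is a U-Net-style decoder taking
skips from stages 1–3 (at H/4, H/8, H/16) under the stage-4 bottom: each
step upsamples bilinearly, concatenates the skip, and mixes with a 3×3
convolution at the skip's width, followed by a refinement block and a 1×1
output convolution (sigmoid for the single-channel pretraining head, softmax
for T-class downstream segmentation).

### Why these internals

The published description fixes the stage table, the block equation and the
pooled attention grid but not the stem form, the inter-stage downsampling,
the SAT inner dimensions or the Transformer MLP widths. Those were resolved
by exact calibration: over a space of standard realisations (stem variant,
bias and norm placement, expansion and MLP ratios, attention dimensions),
the configuration above is the one that reproduces *all* of the published
accounting simultaneously — 3,065,078 / 3,063,272 parameters with/without
SAT modules, a 1,806-parameter SAT budget, and 1.08 GMAC at 3×384×384. The
129-parameters-per-module solution is corroborated independently: inserting
one SAT module into each of the eight basic blocks of ResNet-18 adds
exactly 8 × 129 = 1,032 parameters, matching the published ResNet-18+SAT
count.

### Accounting conventions

`count_parameters` sums trainable scalars. `count_macs` counts convolution
and linear layers only (kernel-area × in-channels/groups × out-channels ×
output positions; in × out × tokens for linear maps); attention
score/value matrix products, normalisations and elementwise operations are
excluded, matching the default behaviour of the common profiler convention.
Under it the ResNet-18 reference measures 5.33 GMAC at 384²; profilers that
additionally count normalisation/activation elementwise operations report
~0.02 GMAC more.

## RCKD pretraining

A frozen teacher maps an RGB patch to a per-pixel nuclei probability map
(`TeacherModel.predict`). Probabilities are thresholded at α = 0.5
(inclusive, `y ≥ α`) into binary pseudo-labels, generated once and cached —
the teacher never changes, so labels are constant across epochs. Image and
pseudo-label are resized to `input_size²` (default 512; bilinear for the
image, nearest-neighbour for the label). The student (backbone + 1-channel
sigmoid decoder) minimises the pixel-averaged binary cross-entropy — for a
two-class map this is exactly the per-pixel cross-entropy, at half the head
cost of a 2-channel softmax.

The optimiser is LARS: local rate `tc·‖p‖/(‖g‖+wd·‖p‖+ε)` per parameter
block (trust coefficient 0.001, weight decay 1e−4, ε = 1e−9, momentum 0.9;
a zero-norm block falls back to ratio 1), a global rate that warms up
linearly from 0 over 10 of 100 epochs (defaults) and decays by cosine
afterwards. The warm-up peak is not a published quantity; the default
(1.0) was chosen so that desk-scale distillation converges and is recorded
in every training log (JSON-lines: epoch, mean loss, rate, seed).

Teacher images are passed in 8-bit RGB ([0, 255]); the student consumes
[0, 1]. The external-teacher adapter is a subprocess contract (input PNG →
16-bit single-channel PNG, 0..65535 ↦ [0, 1]). Nuclei-instance modelling
(star-convex polygons and the like) is outside the teacher contract — only
the probability map matters. One published detail is *not* emulated at desk
scale: the student there is first supervised-pretrained on ImageNet before
distillation; here students start from seeded random initialisation, which
the transfer experiments must be read against.

## Fine-tuning protocol

`replace_head` carries the backbone over bit-identically and attaches a
freshly initialised task head. If `freeze_positional_encoding` (default
true), PEG parameters are excluded from updates. For each of `n_folds`
(default 5) folds with seed `base_seed + fold`, the data are split
stratified-by-class 6:2:2, the model is trained with SGD (momentum 0.9,
weight decay 0, learning rate 1e−4 at the published operating point) on the
focal loss (α = 0.25, γ = 2; clamping at 1e−12 guards log(0)), validation
loss is evaluated each epoch, training stops once `patience` (default 20)
epochs pass without a strict improvement, the best-validation checkpoint is
restored, and the test metric (accuracy or mIoU) is recorded; the report
carries per-fold metrics and their mean. `patience = 0` therefore runs
exactly one epoch. Class imbalance is handled by the focal loss alone — no
re-sampling. Gradients are clipped to a global norm of 1.0 by default: on
the very small batches of desk-scale runs, momentum can otherwise amplify a
run of same-sign gradients until the softmax saturates.

Two numerical points worth recording: parameters and activations are kept
in float64, so softmax probabilities never underflow to exact zero and the
focal/cross-entropy gradient stays live even for confidently wrong
predictions; and the probability clamp in the losses is straight-through
(values clipped, gradients passed), which preserves the fused
softmax-cross-entropy gradient identity.

## Patch pipeline

Large images are tiled into non-overlapping `patch_size²` patches from the
top-left origin in row-major order; partial edge tiles are discarded (an
image smaller than one patch yields an empty list with a warning, not an
error). The tissue filter keeps a patch iff the mean over all pixels and
channels of the 8-bit RGB patch lies in [50, 245], bounds inclusive —
"average intensity" is taken as the overall RGB mean, not a per-channel or
grayscale-weighted mean. Sampling is uniform without replacement and
seed-deterministic. Magnification is metadata only; vendor slide formats
and pyramid decoding are out of scope (inputs are plain raster images).

## Synthetic data: what it emulates, what it does not

`generate_slide` renders an eosin-pink background (RGB ≈ (231, 180, 200))
with Gaussian pixel noise (σ = 8) and hematoxylin-purple elliptical blobs
(RGB ≈ (92, 64, 150), per-slide stain jitter σ = 12) at uniform random
positions and orientations, radii uniform in 4–9 px — nuclei of roughly
5–10 µm at a 20× scale. The default density (1.1 nuclei per 1,000 px²)
yields ≈ 15% nuclear area, a plausible fraction for cellular tissue. The
mask is exactly the rendered ellipse support, so the mock teacher (a lookup
from image to stored mask) is a perfect oracle. Optional Voronoi regions
with class-dependent density provide segmentation ground truth;
classification datasets vary density and stain between classes and are
Bayes-separable by construction (a `min_nuclei` floor can make separation
deterministic). Everything regenerates bitwise from `(params, seed)`.

What passing these tests shows: the pipeline is wired correctly end to end —
pseudo-labels propagate, the student can drive the distillation loss down
and reproduce the teacher on held-out patches, a distilled backbone
transfers better than a random twin, the protocol's bookkeeping (splits,
early stopping, fold averaging) is exact. What it does not show: anything
about real H&E tissue. The generator has no chromatin texture, no touching
or overlapping nuclei with instance boundaries, no stromal/glandular
structure, no stain-normalisation issues, and its classes are far more
separable than cancer-subtype classes; published downstream accuracies are
not reproducible from it and are not targets here.

## Problem sizes in the test suite

Desk-scale runs use a miniature CSAT (widths 8/12/16/24, one block per
stage, one Transformer block in stages 3–4, 4×4 attention grid) on 32×32
patches: 48 training slides for distillation (20 epochs), 12 held-out
slides for mimicry, 20 images per class for the two-class learnability
check (80-epoch budget, patience 25), and 4096×4096 synthetic slides for
the tiling/filtering/sampling checks. These sizes were chosen as the
smallest at which each property is meaningfully exercised (e.g. the
all-background baseline at the mimicry density scores ≈ 0.80, well under
the 0.90 agreement bar).

## Known limitations

* The calibrated internals reproduce the published accounting exactly, but
  other unstated choices (e.g. head counts in the Transformer blocks) are
  degenerate in parameter count and could differ from the original without
  affecting any number checked here.
* The numpy engine is single-threaded per operation and float64; it is
  meant for correctness and desk-scale experiments, not large-scale
  training. `input_size = 512` pretraining works but is slow.
* mIoU uses dataset-level confusion aggregation; per-image averaging (used
  by some benchmarks) gives different values. Classes absent from both
  prediction and truth are excluded from the mean.
* The ResNet-18+SAT insertion point (one module per basic block, applied to
  the residual branch before the addition) reproduces the published
  parameter count but is otherwise a plausible reading, not a specified
  layout.
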