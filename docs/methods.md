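# Methods

This note records the models implemented by `denseinceps`, the design
choices made where the published description leaves freedom, and what
the synthetic test bed does and does not demonstrate.

## The fused architecture

The network is a two-branch convolutional classifier for 227×227×3
inputs, fused at the network level: the branches are trained jointly
and merged by a depth-concatenation node (channel counts add, spatial
sizes must agree) rather than by averaging posterior scores.

**Dense module (71 layers).** A 3×3/stride-2/depth-32 stem with batch
norm and ReLU; nine residual blocks of five layers each (conv, BN,
ReLU, conv, ReLU) whose skip joins are depth concatenations of block
input with block output; 2×2/stride-2 transition convolutions (depths
128, 256, 256) that absorb the concatenation-driven channel growth;
three 3×3/stride-2 max pools; flatten; single-head self-attention.
Block depths: 64/64, 96/64, then 128/128, 128/64, 128/128 after the
first transition, then 256/256 (1×1 + 3×3), 128/128, 256/256, 256/256
(1×1 + 3×3) after the second. Two extra concat junctions realize the
skip connections *between* concatenation layers. The module contains
22 convolutions.

**Inception module (44 layers).** A 1×1/stride-2/depth-16 stem; an
inception block with four parallel branches (1×1; 1×1→1×3; 1×1→3×1;
3×3 stride-1 max-pool→1×1) joined by depth concatenation; a
3×3/stride-2/depth-64 transition; three six-layer inverted residual
blocks (1×1 expand, ReLU, BN, 3×3 grouped conv, 1×1 project, BN) with
concat skips and depths 128→256, 128→256, 256→312; a
3×3/stride-2/depth-256 transition; max pool; global average pool;
flatten; 4-head self-attention. The module's layer subtotal includes
the classifier head (fully connected, softmax, classification) — see
the counting convention below.

**Fusion.** Each branch ends in a 256-dimensional feature vector; the
fusion node concatenates them to 512 and feeds a fully connected layer,
softmax and classification node. Training minimizes the combined
softmax/cross-entropy loss `-t_y + log Σ_j exp(t_j)` (log-sum-exp
stabilized).

### Counting convention

Every declared graph node (input, conv, BN, ReLU, pool, concat,
flatten, attention, FC, softmax, classification) counts as one layer.
The published subtotals (71 + 44 = 115) leave no room for a separately
counted fusion head, so the attribution is frozen as: the dense
subtotal includes the shared input node; the inception subtotal
includes the classifier head; fusion strips the branch heads, merges
the inputs and adds the four fusion-head nodes — 71 + 40 + 4 = 115.
This is the only attribution arithmetically consistent with the stated
subtotals.

### Parameter accounting

conv: `fh·fw·(Cin/groups)·Cout + Cout`; batch norm: `2C`; fully
connected: `din·dout + dout`; self-attention: three square projection
maps of the embedding dimension, plus one output projection when
multi-headed. Two structural details are unstated in the source
description and are frozen here: the fourth late dense residual block
mirrors the first (1×1 then 3×3, depth 256), and all grouped
convolutions use groups = 8. Under these choices the full graph holds
exactly **6,880,029** learnables (6.9 M to two significant figures).
The per-layer plan is reproducible from `build_dense_module` /
`build_inception_module` and is exported verbatim to `arch.json`.

### Padding and width scaling

Stride-1 convolutions and pools use same-padding; stride-2 layers use
valid padding with floor division, which keeps all concatenation
branches spatially aligned. A width-scale factor s multiplies every
channel count (rounded, minimum 1); the layer count is invariant and
the parameter count scales ≈ s². Tests and the desk-scale pipeline use
s = 1/8, at which all grouped-conv widths remain divisible by 8 and the
fused feature width is 64.

### Attention token layout

The flatten node before each attention module denotes a reshape, not a
destruction of structure: the tokens are the spatial positions of the
final feature map and the embedding is the channel vector, giving the
m×n matrix the attention equations expect. Attention output is
mean-pooled over tokens to one embedding-wide vector. After the final
pools the dense branch reaches 1×1 spatial resolution, so its attention
acts on a single token; the module is retained because its projections
are learnable and the graph is audited structurally. dk equals the
embedding dimension (square projections); the inception module's
multi-head node uses 4 heads (head count unstated in the source).

## Training

SGD with momentum on the cross-entropy loss, seeded He-uniform
initialization for convolutions, Xavier-uniform for fully connected
layers and attention projections, ones/zeros for batch norm. The
smaller head scale keeps initial logits moderate, and inputs are
centered at zero (x − 0.5) inside the runtime — removing the DC
component of the [0,1] images conditions the early convolutions and
substantially stabilizes short runs across seeds. A zero-initialized
head was rejected because it starves the trunk of gradient in the
first steps. Full-scale defaults are the
published tuned values (learning rate 1.4e-4, momentum 0.7002,
mini-batch 64); they target long-schedule training. The desk-scale
preset (`RunConfig.desk_scale`) is the configuration the test suite
exercises: width scale 1/8, 10 epochs, learning rate 3e-3, momentum
0.9, batch 16. The hotter setting is needed because the full-scale
triple barely moves a 10-epoch run; batch 16 also bounds the
backward-pass working set at 227×227 resolution. Hyperparameter
search is exposed as a pluggable seeded random-search stub
(`tune_hyperparameters`); the shipped defaults make running it
optional.

All execution happens on a compact NumPy reverse-mode autodiff engine
(`denseinceps.autograd`) providing grouped convolution (im2col + BLAS),
max/global-average pooling, batch normalization, concatenation, matrix
products, softmax and the fused softmax/cross-entropy loss. Every op's
gradient is verified against central differences in the test suite.

## Catch Fish Optimization

A bound-constrained population minimizer. Exploration (first half of
the evaluation budget): each agent either searches independently —
drift `(x_ref − x) · Exp` toward/away from a random reference agent,
where `Exp` is the normalized fitness gap, plus isotropic noise of
radius `S = D·|Exp|·(1 − EFs/MaxEFs)` — or joins a random group of 3–4
agents contracting toward their centroid with per-agent speed n2 ∈
(0,1) and a decaying offset `(1 − 2·EFs/MaxEFs)²·n3`. The choice is
governed by the capture-rate schedule
`â = (1 − 3·EFs/(2·MaxEFs))^(3·EFs/(2·MaxEFs))`. Exploitation (second
half): every agent is redrawn from a Gaussian centered on the best-ever
position with per-dimension **variance** `n4·η·|mean(Fisher) −
Gbest|/3`, n4 ∈ {1,2,3}, η clamped to [0,1] and decaying to 0 at the
budget's end.

Fixed conventions: minimization; clamping (not reflection) at the
bounds; degenerate fitness gap treated as 0; synchronous generations
(group partners read from the pre-update snapshot); one fitness record
per evaluation, so the best-so-far trace has exactly MaxEFs entries and
is non-increasing by construction. Treating the Gaussian's spread
parameter as a variance (its square root is the standard deviation)
follows the description's "overall variance" wording and is what makes
late-stage refinement effective: with the spread used directly as a
standard deviation the sampling radius collapses geometrically with the
population and the optimizer stalls well short of the 1e-2 sphere
criterion.

### Wrapper feature selection

Agents live in [0,1]^d; thresholding at 0.5 yields a binary mask (an
empty mask is repaired by activating the largest coordinate). Fitness
is the stratified 80/20 holdout error of a fixed small network (one
hidden layer of 25 units, 30 full-batch epochs, seeded) plus a sparsity
penalty λ·(selected/d); identical masks are cached, so the evaluation
budget counts evaluations while compute scales with unique masks. A
`repeats` option averages the error over several seed-derived holdout
splits; the pipeline uses 3 repeats because a single small holdout
saturates at zero error and lets the penalty over-prune. On 10-feature
benchmarks the selected mask's fitness matches exhaustive search over
all 1023 masks in roughly 80–95 % of seeds (the optimum is often a
single mask out of 1023 on a plateau of equal-error masks, so the
match rate is draw-dependent).

## Shallow classifier stage and metrics

Five fully connected softmax classifiers distinguished by hidden
layout — NNN [10], MNN [25], SWNN [100], BNN [10,10], TNN [10,10,10]
(widths follow the conventional narrow/medium/wide presets; the source
names the variants but not the widths). Features are standardized
per fit; training is seeded SGD with momentum 0.9, learning rate 1e-3,
200 epochs by default. Evaluation is stratified k-fold (default k=10)
with the confusion matrix pooled across folds. Metrics are macro
averages over classes with non-zero support: accuracy = 100·trace /
total, sensitivity = macro recall, precision = macro precision, F1 =
macro per-class harmonic mean, and FNR = 100 − sensitivity by
construction. Macro (unweighted) averaging is a fixed choice; the
source reports single values without stating the scheme.

## Synthetic phantoms

Each phantom is a dark frame with a bright skull ellipse, a mid-bright
tissue disc, a cortical ribbon whose thickness decreases with stage
(22→10 px) and a central dark ventricle ellipse whose area factor
increases with stage (0.6→1.8), plus per-image center/axis jitter and
Gaussian intensity noise (σ = 0.05). The strictly ordered morphology
makes staging learnable by construction — a single intensity probe in
the widest ventricle region separates the extreme stages — which is
what lets the end-to-end suite assert accuracy at all. The phantoms do
**not** emulate real MRI texture, partial-volume effects, scanner
variation, or anatomical variability; passing the suite demonstrates
that the pipeline's stages are correct and coupled properly, not that
the published accuracy on clinical data is reproduced (that is
explicitly out of scope).

Augmentation balances each training class to an exact target using
horizontal/vertical flips and rotations of ±{5,10,15}° (bilinear, zero
fill, clipped to [0,1]); it runs after the train/test split, on the
training partition only, so test counts are never inflated. The
rotation angles are fixed here; the source names the operation families
without parameters.

## Problem sizes in the test suite

Structural and parameter audits run at full width (no training). The
end-to-end run uses 200 phantoms (5 × 40), a 70/30 stratified split,
3× augmentation of the training partition, 10 epochs at width 1/8, and
10-fold evaluation of the 60-sample test feature set. The
class-balancing contract is additionally checked at the full published
count (510 originals → 4,004) on 32×32 frames, since the counting
contract is independent of image size. Optimizer benchmarks use a 1-D
quadratic (budget 2,000) and 100 seeds of a 5-D sphere (budget 5,000).

## Known limitations

- The dense branch's attention acts on one token after the final pool;
  it contributes learnable projections but its softmax is trivial.
- The published per-block depths cannot be mapped uniquely onto the
  6.9 M parameter total; the frozen manifest is one consistent reading,
  not recovered ground truth.
- Training-time batch statistics vs. inference-time running statistics
  can differ noticeably in very short runs; the desk preset's feature
  extraction uses running statistics accumulated over all 10 epochs.
- `Time` columns in reports are wall-clock and informational only.
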