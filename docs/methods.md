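# Methods

## Problem setting

Sugarcane stem nodes are small, elongated, densely stacked targets on
near-vertical stalks, frequently occluded by leaves and shot under strong
illumination gradients. The package implements a single-class anchor-free
detector family for this regime and the machinery that makes it work at
small object scales: shape-aware box regression, soft suppression,
high-resolution multi-scale fusion, a shared detail-enhanced head, and
structured channel pruning.

## Box geometry and the Shape-IoU loss

Boxes are center-format `(xc, yc, w, h)`; the internal canonical unit is
pixels, with explicit converters to corner and normalized formats (no
silent coercion). The regression loss is

```
loss = (1 − IoU) + dist_shape + ω · Ω_shape
ww = 2 w_gt^s / (w_gt^s + h_gt^s),   hh = 2 h_gt^s / (w_gt^s + h_gt^s)
dist_shape = (hh·Δx² + ww·Δy²) / c²
Ω_shape = Σ_{t ∈ {w,h}} (1 − e^{−ω_t})⁴,
  ω_w = hh·|w−w_gt| / max(w, w_gt),  ω_h = ww·|h−h_gt| / max(h, h_gt)
```

with `c²` the squared diagonal of the smallest box enclosing both
(clamped at machine epsilon for coincident degenerate boxes). Note the
deliberate naming: the *y*-offset is weighted by `ww` and the *x*-offset
by `hh`, and the width-gap term `ω_w` reuses the `hh` weight — the shape
weights describe the ground-truth box, the gap terms the prediction. In
the source formulation one symbol does double duty for the y-weight and
the width-gap term; here they are distinct names (`ww` vs `ω_w`).

Tunables (defaults): `scale s = 0` — the shape-weight exponent; at 0 the
weights collapse to (1, 1) and `dist_shape` reduces to the plain
normalized center distance, the safest degenerate default since no value
is published for it; `α = 1.5` — aspect-penalty sharpness in
`ShapePenalty = exp(−α|w/h − w_gt/h_gt|)`; `ω = 0.5` — weight of the
shape-gap term in the total, following the Shape-IoU formulation this
design builds on (the combination rule is not printed either).

The aspect-penalized similarity `ShapeIoU = IoU · ShapePenalty` is used
as the suppression similarity by default; the training regression loss
uses the additive form above. Both wirings exist (`penalized_shape_iou`
is pure and can be swapped into the loss), the suppression side is where
the penalized product is clearly specified.

All of this code is written against a dispatch layer so the identical
formulas run on numpy arrays (evaluation, suppression) and on autograd
tensors (training); the gradient is verified against central differences
away from the measure-zero `max`/`abs` switch points.

## Suppression

Greedy by descending score with deterministic tie-breaking (larger area,
then lower input index), per class. Three modes:

* hard: remove at `IoU > N_t`, `N_t = 0.5`;
* soft-linear: `s → s(1 − IoU)` when `IoU > N_t` (gated, as specified);
* soft-gaussian-shape: `s → s·exp(−ShapeIoU²/σ)` applied unconditionally
  (the Gaussian variant of this family has no gate; keeping both
  semantics distinct is intentional).

`σ` defaults to 0.5; the source collides the symbol with the
Gaussian-filter scale and never prints the suppression σ, so it is a
config knob. The division is by `σ` with the square on the similarity,
the printed linearization. A `score_floor` of 1e-3 drops fully decayed
boxes so the soft modes terminate; no box is ever removed for overlap
alone.

## Scale-sequence fusion neck with the P2 path

The stock stride-8/16/32 pyramid loses stem nodes whose feature support
is a couple of cells; the neck therefore keeps the stride-4 (P2) tap and
fuses scales in two complementary ways.

**SSFF.** Every level is resized to the P3 grid (hybrid max+average
halving downward, nearest upward), projected to a common width, the three
coarser levels optionally blurred with normalized Gaussians
(`σ = 0.5, 1.0, 2.0`, one octave of scale space; P2 enters unsmoothed to
preserve the detail that motivates the path — smoothing is applied after
resizing), stacked along a new depth axis and fused by a 1×1×1 3-D
convolution + 3-D batch norm + LeakyReLU, then collapsed by a depth
max-pool. The 1×1×1-only kernel follows the reference scale-sequence
block of this fusion family; a 3×3 spatial stage was considered and
dropped — it blows the FLOP budget the printed complexity numbers imply.
The 3-D convolution is realized as a 1×1 2-D convolution over the
depth-unrolled layout, which is arithmetically identical for a unit depth
kernel.

**TFE.** A (finer, mid, coarser) triple is brought to the mid grid
(hybrid max+avg pool down, nearest up — parameter-free, standard for
this family), projected to a common width, concatenated (3C) and fused
back to C by a 1×1 convolution.

**Wiring.** A PANet over P2–P5: TFE encoders feed the top-down P4 and P3
nodes, the P2 node is an upsample-concat branch (there is no finer level
to complete a triple), the bottom-up path re-descends P3→P5, and the SSFF
product is combined into the bottom-up P3 branch by a channel-attention
add (`out = (a+b) · sigmoid(MLP(GAP(a+b)))` — the add block is named but
not defined in the source; an SE-style gate is this package's choice).

## Shared detail-enhanced head

One stem shared by all four levels: per-level 1×1 lateral to the shared
width, then two DEConv+GroupNorm+SiLU stages, then shared 1×1 box
(`4×reg_max` distribution-focal channels) and class projections; a
learnable per-level scalar multiplies the box logits (`scale_init 1.0`).
GroupNorm (16 groups) rather than batch norm: its statistics are
independent of batch composition — the testable core of the small-batch
claim, and the property the suite asserts.

DEConv is five parallel 3×3 branches whose kernels are fixed linear
rearrangements of the learnable parameters: vanilla; central difference
(center tap minus the kernel sum — annihilates constants); angular
difference (each ring tap minus its clockwise neighbour); horizontal and
vertical differences (a 3-vector placed in the first column/row and
subtracted from the last). The rearrangement matrices live in
`canedet/lsdecd.py` next to their constructors. Because all five branches
convolve the same input, the sum re-parameterizes into a single 3×3
kernel (`reparameterize()`, equivalence ≤ 1e-5 in the tests); parameter
and FLOP accounting of the head uses this deploy form, consistent with
the fused-BN convention below.

Distribution-focal regression (`reg_max = 16`) keeps the head drop-in
compatible with the anchor-free decode of the surrounding architecture
family.

## Model assembly and complexity accounting

Three variants: the nano-scale baseline (C3k2/SPPF/C2PSA backbone, stock
neck, three-scale decoupled head), the ASF-P2 intermediate (same backbone,
fusion neck, stock head extended to four scales), and the improved model
(fusion neck + shared head). All use one class.

Parameter totals are reported in **deploy (fused) form**: each
BatchNorm folds into its preceding bias-free convolution, leaving the
weight plus one bias per output channel — the convention detector
complexity tables are printed in (the unfused total for the baseline is
2,590,035 vs 2,582,347 fused, including the 16 frozen distribution-focal
projection weights, which reference summaries count). GFLOPs are
convolution MACs×2 at 640×640; normalizations, activations, pooling,
resizing and attention matrix products count zero, matching the de-facto
profiler convention for this family.

**Width recovery.** The improved variants' channel plan is not published;
the published complexity figures are exact, and they over-determine the
plan. `scripts/derive_widths.py` documents the recovery: the parameter
gap between the stock four-scale head and the shared head depends only on
the P2 branch width, the shared stem width and the *sum* of the bottom-up
widths, which reduces the problem to a small integer search; the
remaining neck budget is landed exactly using the attention bottleneck
width (unit granularity `2·b3+1`), and the GFLOP windows at one printed
decimal select among candidates. The frozen defaults are
`w4=112, w3=32, w2=30, b3=69, b4=161, b5=209, attn_hidden=15` (all-plain
C3k2 blocks) with shared stem width 64. With them the three variants
reproduce the published fused totals and GFLOPs digit for digit, which is
as strong a structural fingerprint as desk-scale reproduction can give.

## LAMP pruning

Scoring: within each coupled channel group, the per-channel ℓ1 weight
magnitudes of the group's producers are aggregated, sorted ascending,
and normalized by their squared tail mass
(`Score(i) = v[i]²/Σ_{j≥i} v[j]²`) — the top channel of every group
scores exactly 1, so scores are comparable across layers without
per-layer ratios. The published score is per-weight while the procedure
is per-channel; this package applies the normalization to the vector of
per-channel ℓ1 magnitudes, the natural structured reading.

Coupling: a tracer mirrors the forward wiring and produces the coupled
groups — residual adds merge groups, concatenations map offsets,
depthwise convolutions tie input to output, the scale-sequence stack
aligns its projections channel-wise, and the split blocks (C3k2/C2PSA)
partition one convolution's output into independently prunable segments
whose widths are bookkept for the forward split. Protected groups are
scored but never pruned: attention interiors (head-dimension
divisibility), the shared head stem (GroupNorm grouping, and the
observation that the head must keep its channels for localization), and
all detection output convolutions (the output contract).

Schedule (defaults as specified): 200 steps, per-layer sparsity cap 1.0,
FLOP speed-up target 3.0, regularization 5e-4 linearly incremented — at
each step the channels nearest the removal frontier are shrunk by
`(1 − reg·t)` before re-scoring, a deterministic emulation of the
sparsity-enforcing regularization phase that needs no sparse training.
The loop removes lowest-score channels until the step's interpolated FLOP
budget is met, then stops when the target ratio is reached; if
protections make the target unreachable the report carries an explicit
flag. Speed-up is measured in FLOPs at 640 input. After the loop, weights
are physically sliced, so the reported post-pruning parameters and GFLOPs
are measured on the actual smaller network. The published post-pruning
operating point depends on the authors' trained weights and is not a
target; the schedule and its invariants are what the suite asserts.

## Training at micro scale

The loop is deliberately small: SGD (lr 0.01, momentum 0.9, weight decay
5e-4), BCE classification, distribution-focal loss on the two bins
flanking each target distance, and the Shape-IoU loss on decoded boxes
(weights 1 / 0.5 / 5). Assignment is static: each target goes to the
pyramid level whose stride is closest to `size/4`, claiming the cells
inside the box nearest its center (≤ 9), center cell always included.
Dynamic task-aligned matching was considered and rejected at this scale:
with a handful of images and epochs its early-training noise dominates.
One master seed fans out to data generation, weight init and batching.

Paper-scale defaults (640 px input, 200 epochs, batch 16) remain the
`RunConfig` defaults. The shipped micro preset — 128 px scenes, 24
images (19 train / 5 val), batch 4, 20 epochs, fine-tuning 8 epochs —
is the package's own choice of a problem size that exercises every
contract in minutes on one CPU; the suite runs it over three seeds.
Under it, training lifts val mAP50 from 0.0 (random init) to roughly
0.25–0.6 depending on seed, pruning at speed-up 2.0 collapses accuracy,
and fine-tuning recovers it — the qualitative behaviour the full-scale
recipe relies on, at toy scale.

## Synthetic scenes

The generator emulates the statistical structure of stem-node imagery:
1–8 textured, shaded, near-vertical stalks; per stalk a run of brighter
transverse bands with width/height ratio in [1.5, 4] (the elongation the
shape-aware machinery targets) and a darker ring line; box labels are
measured from the rendered band mask, so they are tight by construction
(an oracle re-measures them, IoU ≥ 0.9); leaf-shaped occluders are drawn
*after* labels are recorded — partially hidden nodes keep their full
boxes, matching annotation practice. Illumination is a random linear
gradient. Stalk widths span enough range that node areas cover the
COCO-style small/medium/large bins (cutoffs 32², 96² px), so the
size-binned evaluator is exercised in all bins. Three label-preserving
extreme-condition augmentations (dust haze, rain streaks with vertical
smear, strong-light highlight with clipping) stress appearance only.

What the generator does **not** model: real phone-camera geometry,
foliage clutter with true occlusion boundaries, depth-of-field, motion
blur, or any correlation between illumination and stalk appearance.
Passing the micro suite therefore demonstrates that the machinery is
implemented correctly and trainable — not that the accuracy numbers
transfer to field data.

## Evaluation

COCO conventions: greedy per-image matching by descending confidence
(best remaining IoU ≥ threshold wins, each ground truth matched once),
101-point interpolated AP, mAP50 and mAP50:95 (0.50:0.05:0.95), size
bins with ignore semantics for out-of-bin matches. Precision/recall are
reported at the max-F1 point of the confidence sweep unless a fixed
confidence is requested (the source does not state its operating point).
`0/0` rates are defined as 0 with a warning. An independently written
COCOeval-style oracle in the test-suite agrees to 1e-4 on random
synthetic scenes.

## Numerical and engineering notes

* float32 throughout the engine; im2col + BLAS matmul convolutions;
  gradients verified against central differences per op.
* BatchNorm eps 1e-3 / momentum 0.03 (the conventions of the detector
  family whose parameter tables are being reproduced); GroupNorm eps
  1e-5.
* Profiling runs in a shape-only mode (convolutions count MACs and emit
  zeros), so 640-pixel complexity reports cost milliseconds.
* Checkpoints are compressed `.npz` of parameters plus normalization
  buffers; resuming restores weights exactly but restarts optimizer
  momentum. Pruned networks change tensor shapes, so a pruned checkpoint
  is not reloadable into a freshly built graph: keep the dense
  checkpoint and re-run the pruning pass (it is deterministic given the
  weights).
* Known limitations: single-class contract is assumed throughout the
  micro pipeline; suppression is O(n²) per class per image (a top-300
  score cap bounds it at inference); the pruning tracer covers the model
  graphs this package builds, not arbitrary user graphs; train-time
  augmentation (mosaic-style) is not implemented — the synthetic
  generator's diversity stands in at micro scale.
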