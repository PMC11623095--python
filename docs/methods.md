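# Methods

## The operator

Dense self-attention over an `H×W` feature map costs `O((HW)²)` and
window-restricted attention loses cross-window context.  The multi-scale
reconfiguration self-attention (MSR-SA) operator implemented here takes a
third route: it decomposes the dense attention matrix into grouped sparse
sub-attentions with a *fixed key budget*.

For an input map `X ∈ R^{H×W×C}`:

1. **Grouping.** Channels are split evenly into `G` groups,
   `X_i ∈ R^{N×C'}`, `C' = C/G`.  Each group gets its own 1×1 query, key
   and value projections (`C'×C'`).
2. **Localization.** Group `i` tiles the map into non-overlapping
   `S_i×S_i` windows (`ceil(H/S_i)·ceil(W/S_i)` of them; the map is
   zero-padded bottom/right to the next multiple of `S_i` and padded
   positions are flagged).
3. **Dilated sampling.** Each window is sampled on an `M×M` point grid at
   stride `D_i = (S_i−1)/(M−1)` (positions `0, D, 2D, …`), so every window
   contributes exactly `M²` points whatever its size.  `M = 7` by default.
4. **Cross-window fusion.** Samples at the same grid position are reduced
   across windows with a symmetric aggregate σ — max pooling by default
   (mean and a learnable linear weighting are available).  Each fused key
   therefore carries information from the whole image.
5. **Attention.** `softmax(Q_i K_iᵀ / √h_i) V_i` per group with
   `h_i = C'`, then channel concatenation.  Every query attends to exactly
   `M² = 49` fused keys, independent of window size, so cost is linear in
   image area.

Ascending window sides per group (`S = 7, 13, 25, …`, i.e. `D = 1, 2, 4, …`
clamped to the map side) make the groups span fine-to-coarse granularities
simultaneously: that is the multi-scale claim, and the directional test
(`default` schedule vs. all-`D=1` `low` schedule on phantoms with large
structures) probes it empirically at desk scale.

### Geometry conventions and edge cases

* Pixel indices are 0-based row-major; the sampling grid anchors at each
  window's origin.
* `S = D(M−1)+1` must hold exactly; invalid `(S, M, D)` triples are
  configuration errors raised before any computation.
* The `high` preset ("window as large as the map") uses the largest *valid*
  window side not exceeding the map side — map sides such as 56 are not of
  the form `6D+1`, and keeping `M = 7` (hence 49 keys in every preset) takes
  priority over exact coverage.
* Maps smaller than the sampling grid (the 4×4 and 2×2 grids of a 64×64
  input) clamp `M` to the map side; attention degenerates to dense
  attention there, which is also the exact limit the operator is tested
  against (one group, one window, `D=1` equals brute-force dense softmax
  attention to ≤1e−5).
* Padded positions are excluded from max/mean fusion via the validity mask;
  window order never matters for max/mean (the mean is summed in sorted
  order so the invariance is bitwise, not merely numerical).
* Value-path fusion uses the same σ as the key path.

## The network

A U-shaped encoder–decoder of pre-norm transformer blocks whose mixer is
MSR-SA and whose feed-forward is conv-augmented (expand ×4 → 3×3 depthwise
convolution on the spatial grid → GELU → contract):

* **Embedding.** Overlapping 4× patch embedding: 7×7 convolution, stride 4,
  padding 3 (kernel sizes are a configuration default, not a claim).
* **Encoder.** Four stages at grids `H/4 … H/32`; overlapping patch-merging
  (3×3 conv, stride 2) halves the grid and doubles the width between
  stages.  Defaults: widths (64, 128, 320, 512), depths (2, 2, 2, 2),
  groups (1, 2, 5, 8).
* **Context bridge.** Stage outputs are projected to the widest stage's
  channel count, concatenated along tokens, refined by `d = 4` distinct
  blocks (attention windows live on each stage's own 2D grid; the shared
  feed-forward mixes across stages, running its depthwise conv per stage
  grid), then split and restored to their original shapes exactly.
* **Decoder.** Patch-expanding (linear width adjustment + channel-to-space
  shuffle) doubles the grid and halves the width; skip connections
  concatenate the bridge-refined encoder stage and reduce linearly; a final
  4× expansion and linear head produce pixel-aligned class logits.
* Weight init is truncated normal (std 0.02, cut at 2σ), zero biases, with
  an explicit seed; two forwards with the same seed are bitwise identical.

With value projections and feed-forward contractions zeroed (and identity
bridge adapters), every block and the whole bridge are exact identities —
the residual structure is tested in that limit.

## Loss and metrics

Training minimizes `λ·L_dice + (1−λ)·L_ce`, `λ = 0.6`, with
`L_dice = 1 − Σ_k 2 w_k Σ_i p g / (Σ_i p² + Σ_i g²)` (`w_k = 1/K`) and
`L_ce` the per-class binary cross-entropy averaged over classes and pixels.
A dice-only mode (λ ignored) mirrors the cardiac-MR recipe.  Numerical
choices: ε = 1e−5 on the dice denominator, probabilities clamped to
[1e−7, 1−1e−7].

Evaluation reports DSC (percent; classes empty in both masks score 100,
empty in exactly one score 0; the mean is over foreground classes) and
Hausdorff distance (max and 95th-percentile variants; boundary = pixels
with a 4-neighbour outside the mask; empty masks yield NaN with a warning
and are excluded from means; optional mm spacing, default pixel units).

## Optimization recipe

SGD, momentum 0.9, weight decay 1e−4, base LR 0.05, poly decay
`η₀(1−t/T)^p` stepped per iteration with `p = 0.9` (conventional default),
batch 24, up to 400 epochs at input 224 — the benchmark-scale recipe.
Augmentation: random flips, 90° rotations and a small ±20° rotation,
applied jointly to image and mask (flips/90° rotations leave per-class
pixel counts unchanged).  Best-validation parameters are retained;
training aborts with a diagnostic on non-finite loss; runs are reproducible
from the seed.

Training tensors default to float32 (CPU memory-bandwidth, not accuracy,
is the binding constraint); all oracle comparisons and metrics run in
float64.

## Synthetic phantoms

`PhantomSpec` generates 64×64 (configurable) multi-class slices: a large
ellipse (major diameter > the largest first-stage window, exercising
long-range fusion), a thin 2–3 px annulus encircling it (the concentric
layout of cardiac structures; exercises boundary metrics), and 2–4 disks of
radius < 3 px (finer than the 7-point sampling grid).  Foreground classes
never overlap (rejection sampling with retries; an infeasible packing
raises).  Intensities are per-class means (0.20, 0.45, 0.70, 0.95) plus
Gaussian noise of σ = 0.15, leaving adjacent classes ≈1.7σ apart — roughly
20% of pixels per adjacent-class pair are misassigned by any
intensity-threshold rule, so spatial context is required, which is what
makes the attention mechanism non-trivial to the task.  Phantoms are
deterministic in the seed, bit for bit.

What phantoms do *not* emulate: anatomical texture, partial-volume effects,
scanner artifacts, 3D continuity, inter-subject variability.  Passing the
desk-scale tests therefore demonstrates that the architecture, losses and
training loop are correct and can learn multi-scale structure from context
— not clinical-grade performance.

## Desk-scale study conditions

The smoke configuration (widths 16/32/64/128, depths 1, bridge `d = 2`,
groups 2/2/4/8 so the top stage actually carries two dilation scales,
64×64 inputs) trains with the same SGD recipe for 800 iterations at batch 8
on 40 phantoms, evaluating 20 held-out phantoms; the learning-sanity bar is
mean foreground DSC ≥ 85%.  The directional multi-scale check trains
3 seeds × {default, low} for 150 iterations at batch 4 and compares
seed-averaged held-out DSC.  It runs on 96×96 phantoms rather than 64×64:
on a 16×16 stage grid the larger S=13 windows pad 16→26, so most sampled
positions are padding and the schedule comparison is confounded; 24×24 is
the smallest stage grid that carries the two window scales cleanly.
Problem sizes were chosen so the full suite runs on a single CPU in well
under half an hour.

## Known limitations

* 2D slices only; volumes are segmented slice-wise.
* No pretraining; a checkpoint can be supplied but nothing here requires
  one.  Benchmark-scale accuracy claims are out of scope at desk scale.
* The NumPy autodiff core is deliberately minimal (no graph optimization,
  single-threaded); it is sized for the smoke models, not for 224-input
  default-width training.
* Linear fusion ties its window-weight vector to a fixed grid size, so the
  parameter count under `linear` (unlike `max`/`mean`) depends on the
  window schedule.
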