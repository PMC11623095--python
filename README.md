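# msrunet

Multi-scale reconfiguration self-attention U-Net for 2D medical image
segmentation — a transformer encoder–decoder for CT/MR slices (multi-organ
abdominal CT, cardiac MR and similar tasks) whose attention operator keeps
a fixed key budget while seeing the whole image at several granularities at
once.  Written for researchers who want the operator, the network, the
losses/metrics and a reproducible CPU-scale test bed in plain scientific
Python (NumPy; no GPU framework required).

## The idea

Window-based self-attention is cheap but near-sighted.  MSR-SA
(multi-scale reconfiguration self-attention) decomposes dense attention
into grouped sparse sub-attentions:

* channels split into `G` groups, `C' = C/G`, with per-group 1×1
  projections `W^Q, W^K, W^V`;
* group `i` tiles the map into non-overlapping `S_i×S_i` windows and
  samples an `M×M` grid per window at dilation `D_i = (S_i−1)/(M−1)`
  (`M = 7`);
* samples at the same grid position are fused across windows by a
  symmetric aggregate σ (max pooling by default), giving
  `K_i, V_i ∈ R^{M²×C'}`;
* each group computes `softmax(Q_i K_iᵀ/√h_i) V_i` and the groups are
  concatenated.

Every query attends to exactly `M² = 49` image-spanning keys whatever the
window size; ascending `S_i` per group (7, 13, 25, …) makes the groups
cover fine-to-coarse scales simultaneously.  Around this operator the
package builds a U-shaped network (overlapping 4× patch embedding, four
encoder stages with patch merging, a context bridge that refines all
stages jointly, a decoder with skip connections and a 4× expansion head),
the hybrid loss `0.6·L_dice + 0.4·L_ce`, DSC/Hausdorff evaluation, an SGD +
poly-LR training loop, and a deterministic multi-scale phantom generator.

## Worked example

```bash
python examples/05_smoke_training.py
```

trains the small configuration (≈0.9 M parameters) on 20 synthetic
phantoms and evaluates 10 held-out ones:

```
model: 883,204 parameters
iter  100  lr 0.0349  loss 0.3864  val DSC 28.4%
iter  200  lr 0.0188  loss 0.2765  val DSC 49.7%
iter  300  lr 0.0003  loss 0.2276  val DSC 54.6%
best held-out mean foreground DSC: 54.6% (iteration 300)
```

The loss is the hybrid dice/cross-entropy objective; "val DSC" is the mean
foreground dice similarity (in %) over held-out phantoms — chance level for
these three structures is near zero, and longer schedules (800 iterations,
batch 8, as in the acceptance run) push it close to 90%.  The other
examples are seconds-fast: `01` verifies the operator against brute-force
dense attention, `02` prints the window/dilation schedules, `03` walks one
DSC/Hausdorff computation, `04` inspects a phantom.

There is also a thin CLI:

```bash
msrunet make-phantoms --n 20 --seed 0 --out data/
msrunet train --data data/ --out run/ --preset smoke --iters 300
msrunet evaluate --data data/ --checkpoint run/checkpoint.npz --out eval/
msrunet predict --input data/ --checkpoint run/checkpoint.npz --out pred/
```

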