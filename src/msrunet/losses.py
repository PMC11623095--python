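"""Segmentation losses: dice, per-class binary cross-entropy, and their
convex combination.

With probabilities ``p(k, i)`` and one-hot ground truth ``g(k, i)`` over
``K`` classes and ``N`` pixels:

* dice loss: ``1 - Σ_k 2 w_k Σ_i p g / (Σ_i p² + Σ_i g²)`` with
  ``Σ_k w_k = 1`` (default ``w_k = 1/K``),
* cross-entropy: mean over classes and pixels of
  ``-[g log p + (1-g) log(1-p)]`` with probability clamping,
* hybrid: ``λ·L_dice + (1-λ)·L_ce`` (default ``λ = 0.6``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor

__all__ = ["LossConfig", "one_hot", "dice_loss", "ce_loss", "hybrid_loss"]

_SMOOTH = 1e-5
_P_CLAMP = 1e-7


@dataclass(frozen=True)
class LossConfig:
    """Class count, per-class weights (sum to 1) and the dice/CE mixing
    factor λ ∈ [0, 1]."""

    num_classes: int
    weights: tuple | None = None
    lam: float = 0.6

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {self.lam}")
        if self.num_classes < 1:
            raise ValueError("need at least one class")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (self.num_classes,):
                raise ValueError(
                    f"weights shape {w.shape} != ({self.num_classes},)"
                )
            if not np.isclose(w.sum(), 1.0):
                raise ValueError(f"class weights must sum to 1, got {w.sum()}")

    @property
    def class_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.full(self.num_classes, 1.0 / self.num_classes)
        return np.asarray(self.weights, dtype=float)


def one_hot(mask: np.ndarray, K: int) -> np.ndarray:
    """Integer label mask → one-hot array with a trailing class axis."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() >= K:
        raise ValueError(
            f"labels outside [0, {K - 1}]: found range "
            f"[{mask.min()}, {mask.max()}]"
        )
    return np.eye(K, dtype=np.float64)[mask]


def _flatten(p, g, K: int):
    pt = p if isinstance(p, Tensor) else Tensor(p)
    ga = np.asarray(g, dtype=np.float64)
    if pt.shape[-1] != K:
        raise ValueError(f"probabilities have {pt.shape[-1]} classes, config has {K}")
    if ga.ndim == pt.ndim - 1:  # integer labels
        ga = one_hot(ga.astype(int), K)
    if ga.shape != pt.shape:
        raise ValueError(f"shape mismatch: probs {pt.shape} vs labels {ga.shape}")
    n = int(np.prod(pt.shape[:-1]))
    return pt.reshape(n, K), ga.reshape(n, K)


def dice_loss(p, g, cfg: LossConfig) -> Tensor:
    """Soft multi-class dice loss; 0 for a perfect one-hot prediction, 1 for
    a fully disjoint one.  The denominator carries a small smoothing term so
    classes empty in both prediction and truth are safe."""
    pt, ga = _flatten(p, g, cfg.num_classes)
    w = Tensor(cfg.class_weights)
    inter = (pt * Tensor(ga)).sum(axis=0)
    denom = (pt * pt).sum(axis=0) + Tensor((ga * ga).sum(axis=0)) + _SMOOTH
    return 1.0 - (w * 2.0 * inter / denom).sum()


def ce_loss(p, g, num_classes: int | None = None) -> Tensor:
    """Per-class binary cross-entropy averaged over classes and pixels,
    with probabilities clamped to ``[1e-7, 1 - 1e-7]``."""
    K = num_classes if num_classes is not None else (
        p.shape[-1] if isinstance(p, Tensor) else np.asarray(p).shape[-1]
    )
    pt, ga = _flatten(p, g, K)
    pc = pt.clip(_P_CLAMP, 1.0 - _P_CLAMP)
    gt = Tensor(ga)
    n = pt.shape[0]
    terms = gt * pc.log() + (1.0 - gt) * (1.0 - pc).log()
    return -terms.sum() * (1.0 / (n * K))


def hybrid_loss(p, g, cfg: LossConfig) -> Tensor:
    """``λ·L_dice + (1-λ)·L_ce`` — the class-imbalance-aware training loss."""
    return cfg.lam * dice_loss(p, g, cfg) + (1.0 - cfg.lam) * ce_loss(
        p, g, cfg.num_classes
    )
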