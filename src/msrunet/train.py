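"""Training loop: SGD with momentum, poly learning-rate decay, hybrid or
dice-only loss, joint image/mask augmentation, best-validation selection.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .autograd import default_dtype, softmax
from .losses import LossConfig, dice_loss, hybrid_loss
from .metrics import dsc_metric
from .model import MSRUNet
from .nn import SGD

__all__ = ["TrainConfig", "TrainResult", "poly_lr", "augment_pair", "train", "validate_dsc"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe.  Defaults follow the benchmark settings (input
    224, SGD lr 0.05 / momentum 0.9 / weight decay 1e-4, poly decay, batch
    24, 400 epochs, λ=0.6); ``max_iters`` caps the schedule for desk-scale
    runs.  ``loss_mode='dice'`` ignores λ entirely."""

    input_side: int = 224
    base_lr: float = 0.05
    poly_power: float = 0.9
    max_epochs: int = 400
    max_iters: int | None = None
    batch_size: int = 24
    momentum: float = 0.9
    weight_decay: float = 1e-4
    lam: float = 0.6
    loss_mode: str = "hybrid"
    seed: int = 0
    augment: bool = True
    small_rotation: bool = True
    val_interval: int = 100
    dtype: str = "float32"  # training precision; metrics are dtype-agnostic

    def __post_init__(self):
        if self.base_lr <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("learning rate, batch size and epochs must be positive")
        if self.loss_mode not in ("hybrid", "dice"):
            raise ValueError(f"loss_mode must be 'hybrid' or 'dice', got {self.loss_mode!r}")


@dataclass
class TrainResult:
    history: list
    best_val_dsc: float
    best_iter: int
    best_state: dict
    initial_loss: float
    final_loss: float


def poly_lr(t: int, T: int, base: float = 0.05, power: float = 0.9) -> float:
    """Poly schedule ``base * (1 - t/T)^power``; monotone non-increasing,
    base at t=0 and exactly 0 at t=T.  t beyond T clamps to 0 with a
    warning."""
    if t < 0:
        raise ValueError(f"step t must be >= 0, got {t}")
    if t > T:
        warnings.warn(f"step {t} beyond schedule end {T}; clamping LR to 0", stacklevel=2)
        return 0.0
    return base * (1.0 - t / T) ** power


def augment_pair(image, mask, rng: np.random.Generator, small_rotation: bool = True):
    """Random flips, 90° rotations and (optionally) a small ±20° rotation,
    applied jointly to image and mask.  Flips/90° rotations keep per-class
    pixel counts unchanged; the small rotation resamples (nearest neighbour
    for labels)."""
    if rng.random() < 0.5:
        image, mask = image[::-1], mask[::-1]
    if rng.random() < 0.5:
        image, mask = image[:, ::-1], mask[:, ::-1]
    k = int(rng.integers(0, 4))
    if k:
        image, mask = np.rot90(image, k), np.rot90(mask, k)
    if small_rotation and rng.random() < 0.5:
        angle = rng.uniform(-20.0, 20.0)
        image = ndimage.rotate(image, angle, reshape=False, order=1, mode="nearest")
        mask = ndimage.rotate(mask, angle, reshape=False, order=0, mode="nearest")
    return np.ascontiguousarray(image), np.ascontiguousarray(mask)


def validate_dsc(model: MSRUNet, cases, K: int) -> float:
    """Mean foreground DSC (%) of argmax predictions over (image, mask) pairs."""
    images = np.stack([im for im, _ in cases])
    preds = model.predict(images)
    return float(np.mean([
        dsc_metric(pred, mask, K)["mean_foreground"]
        for pred, (_, mask) in zip(preds, cases)
    ]))


def train(
    model: MSRUNet,
    dataset,
    cfg: TrainConfig,
    log_path: str | Path | None = None,
    verbose: bool = False,
) -> TrainResult:
    """Optimize ``model`` on ``dataset`` (object with ``train``/``val`` lists
    of (image, mask) pairs).  Fully reproducible given ``cfg.seed``; aborts
    with a diagnostic on NaN loss; retains the best-validation parameters.
    """
    if not dataset.train:
        raise ValueError("empty training set")
    with default_dtype(cfg.dtype):
        return _train_impl(model.astype(cfg.dtype), dataset, cfg, log_path, verbose)


def _train_impl(model, dataset, cfg, log_path, verbose=False):
    rng = np.random.default_rng(cfg.seed)
    K = model.num_classes
    loss_cfg = LossConfig(num_classes=K, lam=cfg.lam)
    opt = SGD(model.parameters(), lr=cfg.base_lr,
              momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    steps_per_epoch = math.ceil(len(dataset.train) / cfg.batch_size)
    T = cfg.max_iters if cfg.max_iters is not None else cfg.max_epochs * steps_per_epoch

    history: list[dict] = []
    best = {"dsc": -1.0, "iter": -1, "state": model.state_dict()}
    initial_loss = final_loss = float("nan")
    order = rng.permutation(len(dataset.train))
    cursor = 0
    for t in range(T):
        idx = []
        for _ in range(min(cfg.batch_size, len(dataset.train))):
            if cursor == len(order):
                order = rng.permutation(len(dataset.train))
                cursor = 0
            idx.append(order[cursor])
            cursor += 1
        imgs, masks = [], []
        for i in idx:
            im, mk = dataset.train[i]
            if cfg.augment:
                im, mk = augment_pair(im, mk, rng, cfg.small_rotation)
            imgs.append(im)
            masks.append(mk)
        batch = np.stack(imgs)
        target = np.stack(masks)

        logits = model.forward(batch)
        probs = softmax(logits, axis=-1)
        if cfg.loss_mode == "dice":
            loss = dice_loss(probs, target, loss_cfg)
        else:
            loss = hybrid_loss(probs, target, loss_cfg)
        loss_val = loss.item()
        if not np.isfinite(loss_val):
            raise RuntimeError(
                f"non-finite loss {loss_val} at iteration {t} (lr={opt.lr:.4g}); "
                "aborting — lower the learning rate or check the inputs"
            )
        if t == 0:
            initial_loss = loss_val
        final_loss = loss_val
        opt.zero_grad()
        loss.backward()
        opt.lr = poly_lr(t, T, cfg.base_lr, cfg.poly_power)
        opt.step()

        if dataset.val and ((t + 1) % cfg.val_interval == 0 or t == T - 1):
            vdsc = validate_dsc(model, dataset.val, K)
            history.append({"iter": t + 1, "lr": opt.lr, "loss": loss_val,
                            "val_dsc": vdsc})
            if verbose:
                print(f"iter {t + 1:5d}  lr {opt.lr:.4f}  loss {loss_val:.4f}  "
                      f"val DSC {vdsc:.2f}%")
            if vdsc > best["dsc"]:
                best = {"dsc": vdsc, "iter": t + 1, "state": model.state_dict()}
        elif (t + 1) % 20 == 0 or t == T - 1:
            history.append({"iter": t + 1, "lr": opt.lr, "loss": loss_val,
                            "val_dsc": float("nan")})

    if best["iter"] >= 0:
        model.load_state_dict(best["state"])
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["iter", "lr", "loss", "val_dsc"])
            writer.writeheader()
            for row in history:
                writer.writerow(row)
    return TrainResult(
        history=history,
        best_val_dsc=best["dsc"],
        best_iter=best["iter"],
        best_state=best["state"],
        initial_loss=initial_loss,
        final_loss=final_loss,
    )
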