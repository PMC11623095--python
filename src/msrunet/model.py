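"""The full U-shaped segmentation network.

Encoder: overlapping 4× patch embedding, then four stages of reconfiguration
transformer blocks separated by overlapping patch-merging layers (grids
H/4, H/8, H/16, H/32).  The four stage outputs pass through the context
bridge, feed the decoder through skip connections (channel concatenation +
linear reduction), and a final 4× expansion projects tokens back to
pixel-level class logits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attention import ConfigurationError, auto_group_specs
from .autograd import Tensor, concat, no_grad, softmax
from .blocks import FinalExpandProject, OverlapPatchEmbed, PatchExpand, PatchMerge, ReconfigBlock
from .bridge import BridgeConfig, ContextBridge
from .nn import Linear, Module

__all__ = ["StagePlan", "MSRUNet"]


@dataclass(frozen=True)
class StagePlan:
    """Per-stage widths, block depths and attention group counts (4 encoder
    stages, mirrored by 3 decoder stages), plus bridge depth d."""

    widths: tuple = (64, 128, 320, 512)
    depths: tuple = (2, 2, 2, 2)
    groups: tuple = (1, 2, 5, 8)
    bridge_depth: int = 4
    ffn_ratio: int = 4

    def __post_init__(self):
        if not (len(self.widths) == len(self.depths) == len(self.groups) == 4):
            raise ConfigurationError("StagePlan needs exactly 4 stages")
        for w, d, g in zip(self.widths, self.depths, self.groups):
            if d < 1:
                raise ConfigurationError(f"depths must be >= 1, got {d}")
            if g < 1 or w % g != 0:
                raise ConfigurationError(f"width {w} not divisible by {g} groups")
        if self.bridge_depth < 1:
            raise ConfigurationError("bridge depth must be >= 1")

    @classmethod
    def small(cls) -> "StagePlan":
        """Desk-scale plan for CPU smoke training."""
        return cls(widths=(16, 32, 64, 128), depths=(1, 1, 1, 1),
                   groups=(2, 2, 4, 8), bridge_depth=2)


class MSRUNet(Module):
    """Multi-scale reconfiguration U-Net for 2D slice segmentation."""

    def __init__(
        self,
        plan: StagePlan | None = None,
        num_classes: int = 9,
        img_size: int | tuple[int, int] = 224,
        in_ch: int = 1,
        fusion: str = "max",
        preset: str = "default",
        seed: int = 0,
    ):
        super().__init__()
        plan = plan or StagePlan()
        if isinstance(img_size, int):
            img_size = (img_size, img_size)
        H, W = img_size
        if H % 32 or W % 32:
            raise ConfigurationError(
                f"image size {H}x{W} must be divisible by 32 "
                f"(pad to {-(-H // 32) * 32}x{-(-W // 32) * 32})"
            )
        self.plan = plan
        self.num_classes = num_classes
        self.img_size = (H, W)
        self.fusion = fusion
        self.preset = preset
        rng = np.random.default_rng(seed)
        hws = [(H // f, W // f) for f in (4, 8, 16, 32)]
        self.stage_hws = hws

        def make_blocks(stage: int, depth: int):
            w = plan.widths[stage]
            specs = auto_group_specs(*hws[stage], w, plan.groups[stage], preset=preset)
            return [
                ReconfigBlock(w, specs, fusion=fusion, ffn_ratio=plan.ffn_ratio,
                              rng=rng, grid_hw=hws[stage])
                for _ in range(depth)
            ]

        self.embed = OverlapPatchEmbed(in_ch, plan.widths[0], rng=rng)
        self.enc1 = make_blocks(0, plan.depths[0])
        self.enc2 = make_blocks(1, plan.depths[1])
        self.enc3 = make_blocks(2, plan.depths[2])
        self.enc4 = make_blocks(3, plan.depths[3])
        self.merge1 = PatchMerge(plan.widths[0], plan.widths[1], rng=rng)
        self.merge2 = PatchMerge(plan.widths[1], plan.widths[2], rng=rng)
        self.merge3 = PatchMerge(plan.widths[2], plan.widths[3], rng=rng)
        self.bridge = ContextBridge(
            plan.widths, hws, plan.groups,
            BridgeConfig(plan.bridge_depth, fusion, preset), rng=rng,
        )
        self.expand3 = PatchExpand(plan.widths[3], rng=rng)
        self.expand2 = PatchExpand(plan.widths[2], rng=rng)
        self.expand1 = PatchExpand(plan.widths[1], rng=rng)
        self.reduce3 = Linear(plan.widths[3] // 2 + plan.widths[2], plan.widths[2], rng=rng)
        self.reduce2 = Linear(plan.widths[2] // 2 + plan.widths[1], plan.widths[1], rng=rng)
        self.reduce1 = Linear(plan.widths[1] // 2 + plan.widths[0], plan.widths[0], rng=rng)
        self.dec3 = make_blocks(2, plan.depths[2])
        self.dec2 = make_blocks(1, plan.depths[1])
        self.dec1 = make_blocks(0, plan.depths[0])
        self.final = FinalExpandProject(plan.widths[0], num_classes, rng=rng)

    # ------------------------------------------------------------------ pass
    def encode(self, image) -> list[Tensor]:
        t = image if isinstance(image, Tensor) else Tensor(np.asarray(image, dtype=np.float64))
        if t.ndim == 2:
            t = t.reshape((1,) + t.shape)
        H, W = t.shape[1], t.shape[2]
        if (H, W) != self.img_size:
            raise ConfigurationError(
                f"model built for {self.img_size[0]}x{self.img_size[1]} inputs, "
                f"got {H}x{W}"
            )
        tokens, hw = self.embed(t)
        skips = []
        for blocks, merge in (
            (self.enc1, self.merge1),
            (self.enc2, self.merge2),
            (self.enc3, self.merge3),
            (self.enc4, None),
        ):
            for b in blocks:
                tokens = b(tokens, hw)
            skips.append(tokens)
            if merge is not None:
                tokens, hw = merge(tokens, hw)
        return skips

    def forward(self, image) -> Tensor:
        skips = self.encode(image)
        bridged = self.bridge(skips)
        x, hw = bridged[3], self.stage_hws[3]
        for expand, reduce, blocks, s in (
            (self.expand3, self.reduce3, self.dec3, 2),
            (self.expand2, self.reduce2, self.dec2, 1),
            (self.expand1, self.reduce1, self.dec1, 0),
        ):
            x, hw = expand(x, hw)
            x = reduce(concat([x, bridged[s]], axis=-1))
            for b in blocks:
                x = b(x, hw)
        return self.final(x, hw)  # (B, H, W, K) logits

    def predict_proba(self, image) -> np.ndarray:
        with no_grad():
            logits = self.forward(image)
            return softmax(logits, axis=-1).data

    def predict(self, image) -> np.ndarray:
        """Argmax label mask(s) for one image or a batch."""
        proba = self.predict_proba(image)
        labels = proba.argmax(axis=-1)
        return labels[0] if np.asarray(image).ndim == 2 else labels
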