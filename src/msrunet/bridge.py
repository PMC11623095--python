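"""Reconfiguration transformer context bridge.

Encoder stage outputs are flattened, projected to a common channel width,
concatenated along the token axis, refined by ``d`` reconfiguration blocks,
then split and restored to their per-stage shapes.  Attention windows are
defined on each stage's own 2D grid (a concatenated multi-resolution
sequence has no single window geometry); token mixing across stages happens
in the shared feed-forward weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attention import ConfigurationError, MSRAttention, auto_group_specs
from .autograd import Tensor, concat
from .nn import DepthwiseConv2d, LayerNorm, Linear, Module

__all__ = ["BridgeConfig", "bridge_pack", "bridge_unpack", "BridgeBlock", "ContextBridge"]


@dataclass(frozen=True)
class BridgeConfig:
    """Bridge hyper-parameters: number of refinement loops ``d`` (default 4,
    realized as distinct blocks), fusion mode and dilation preset shared with
    the rest of the network."""

    depth: int = 4
    fusion: str = "max"
    preset: str = "default"

    def __post_init__(self):
        if self.depth < 1:
            raise ConfigurationError(f"bridge depth must be >= 1, got {self.depth}")


def bridge_pack(stage_tokens: list[Tensor], stage_hws: list[tuple[int, int]]):
    """Concatenate per-stage token sequences; returns the packed sequence and
    the split plan ``[(N_s, (H_s, W_s)), ...]`` that inverts the packing."""
    if len(stage_tokens) == 0:
        raise ConfigurationError("bridge_pack requires at least one stage map")
    ts = [t if isinstance(t, Tensor) else Tensor(t) for t in stage_tokens]
    plan = []
    for t, hw in zip(ts, stage_hws):
        if t.shape[1] != hw[0] * hw[1]:
            raise ConfigurationError(
                f"stage tokens {t.shape[1]} != H*W = {hw[0] * hw[1]}"
            )
        plan.append((t.shape[1], tuple(hw)))
    if len(ts) == 1:
        return ts[0], plan
    return concat(ts, axis=1), plan


def bridge_unpack(packed: Tensor, plan) -> list[Tensor]:
    """Split a packed sequence back into per-stage sequences."""
    total = sum(n for n, _ in plan)
    if packed.shape[1] != total:
        raise ConfigurationError(
            f"packed length {packed.shape[1]} != plan total {total}"
        )
    out, off = [], 0
    for n, _ in plan:
        out.append(packed[:, off : off + n, :])
        off += n
    return out


class BridgeBlock(Module):
    """One bridge refinement loop: per-stage MSR-SA on the stage grids, then
    a shared conv feed-forward over the packed sequence."""

    def __init__(self, dim, stage_hws, stage_groups, cfg: BridgeConfig, rng=None, ffn_ratio=4):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = [
            MSRAttention(
                dim,
                auto_group_specs(h, w, dim, g, preset=cfg.preset),
                fusion=cfg.fusion,
                rng=rng,
                grid_hw=(h, w),
            )
            for (h, w), g in zip(stage_hws, stage_groups)
        ]
        hidden = dim * ffn_ratio
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, hidden, rng=rng)
        self.dwconv = DepthwiseConv2d(hidden, rng=rng)
        self.fc2 = Linear(hidden, dim, rng=rng)

    def zero_residual_branches(self) -> None:
        for attn in self.attn:
            for lin in attn.v_proj:
                lin.weight.data[:] = 0.0
                lin.bias.data[:] = 0.0
        self.fc2.weight.data[:] = 0.0
        self.fc2.bias.data[:] = 0.0

    def forward(self, packed: Tensor, plan) -> Tensor:
        stages = bridge_unpack(self.norm1(packed), plan)
        attended = []
        for attn, x_s, (n, (h, w)) in zip(self.attn, stages, plan):
            B = x_s.shape[0]
            a = attn(x_s.reshape(B, h, w, x_s.shape[-1]))
            attended.append(a.reshape(B, n, a.shape[-1]))
        packed = packed + concat(attended, axis=1)
        # shared FFN; depthwise conv runs on each stage's own grid
        y = self.fc1(self.norm2(packed))
        pieces = []
        for y_s, (n, (h, w)) in zip(bridge_unpack(y, plan), plan):
            B = y_s.shape[0]
            c = self.dwconv(y_s.reshape(B, h, w, y_s.shape[-1]))
            pieces.append(c.reshape(B, n, c.shape[-1]))
        y = concat(pieces, axis=1).gelu()
        return packed + self.fc2(y)


class ContextBridge(Module):
    """Pack → refine (d blocks) → split-and-restore over encoder stages.

    The common width is the widest stage's channels; linear adapters map each
    stage in and out, so per-stage output shapes equal the input shapes.
    """

    def __init__(self, stage_dims, stage_hws, stage_groups, cfg: BridgeConfig | None = None, rng=None):
        super().__init__()
        if len(stage_dims) == 0:
            raise ConfigurationError("bridge requires at least one stage")
        cfg = cfg or BridgeConfig()
        self.cfg = cfg
        self.stage_dims = list(stage_dims)
        self.stage_hws = [tuple(hw) for hw in stage_hws]
        dim = max(stage_dims)
        self.dim = dim
        self.ad_in = [Linear(c, dim, rng=rng) for c in stage_dims]
        self.ad_out = [Linear(dim, c, rng=rng) for c in stage_dims]
        self.blocks = [
            BridgeBlock(dim, self.stage_hws, stage_groups, cfg, rng=rng)
            for _ in range(cfg.depth)
        ]

    def zero_residual_branches(self) -> None:
        for b in self.blocks:
            b.zero_residual_branches()

    def set_identity_adapters(self) -> None:
        """Make the in/out channel adapters exact (pseudo)inverses; with
        zeroed branches the whole bridge is then the identity."""
        for lin_in, lin_out, c in zip(self.ad_in, self.ad_out, self.stage_dims):
            lin_in.weight.data = np.eye(c, self.dim)
            lin_in.bias.data[:] = 0.0
            lin_out.weight.data = np.eye(self.dim, c)
            lin_out.bias.data[:] = 0.0

    def forward(self, stage_tokens: list[Tensor]) -> list[Tensor]:
        if len(stage_tokens) != len(self.stage_dims):
            raise ConfigurationError(
                f"expected {len(self.stage_dims)} stages, got {len(stage_tokens)}"
            )
        for t, c, hw in zip(stage_tokens, self.stage_dims, self.stage_hws):
            if t.shape[-1] != c or t.shape[1] != hw[0] * hw[1]:
                raise ConfigurationError(
                    f"stage shape {tuple(t.shape)} does not match "
                    f"configured (N={hw[0] * hw[1]}, C={c})"
                )
        xs = [ad(t) for ad, t in zip(self.ad_in, stage_tokens)]
        packed, plan = bridge_pack(xs, self.stage_hws)
        for block in self.blocks:
            packed = block(packed, plan)
        return [ad(t) for ad, t in zip(self.ad_out, bridge_unpack(packed, plan))]
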