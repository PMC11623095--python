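"""Reconfiguration transformer blocks and resolution-changing layers.

Tokens are ``(B, N, C)`` sequences carrying spatial metadata ``(H, W)`` with
``N = H*W``; reshaping between the two views is lossless.  A reconfiguration
block is pre-norm: ``x + MSR-SA(LN(x))`` then ``x + ConvFFN(LN(x))`` where
the feed-forward expands ×4, applies a 3×3 depthwise convolution on the
spatial grid, and contracts back.
"""

from __future__ import annotations

from .attention import ConfigurationError, GroupSpec, MSRAttention
from .autograd import Tensor
from .nn import Conv2d, DepthwiseConv2d, LayerNorm, Linear, Module

__all__ = [
    "ConvFFN",
    "ReconfigBlock",
    "OverlapPatchEmbed",
    "PatchMerge",
    "PatchExpand",
    "FinalExpandProject",
]


class ConvFFN(Module):
    """Feed-forward with a depthwise 3×3 convolution between the two linears."""

    def __init__(self, dim: int, ratio: int = 4, rng=None):
        super().__init__()
        hidden = dim * ratio
        self.fc1 = Linear(dim, hidden, rng=rng)
        self.dwconv = DepthwiseConv2d(hidden, rng=rng)
        self.fc2 = Linear(hidden, dim, rng=rng)

    def forward(self, tokens: Tensor, hw: tuple[int, int]) -> Tensor:
        H, W = hw
        B, N, _ = tokens.shape
        h = self.fc1(tokens)
        h = h.reshape(B, H, W, h.shape[-1])
        h = self.dwconv(h)
        h = h.reshape(B, N, h.shape[-1]).gelu()
        return self.fc2(h)


class ReconfigBlock(Module):
    """Pre-norm transformer block whose mixer is MSR-SA."""

    def __init__(
        self,
        dim: int,
        specs: list[GroupSpec],
        fusion: str = "max",
        ffn_ratio: int = 4,
        rng=None,
        grid_hw: tuple[int, int] | None = None,
    ):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = MSRAttention(dim, specs, fusion=fusion, rng=rng, grid_hw=grid_hw)
        self.norm2 = LayerNorm(dim)
        self.ffn = ConvFFN(dim, ratio=ffn_ratio, rng=rng)

    def zero_residual_branches(self) -> None:
        """Zero the branch outputs so the block becomes an exact identity
        (value projections and the FFN contraction are zeroed)."""
        for lin in self.attn.v_proj:
            lin.weight.data[:] = 0.0
            lin.bias.data[:] = 0.0
        self.ffn.fc2.weight.data[:] = 0.0
        self.ffn.fc2.bias.data[:] = 0.0

    def forward(self, tokens: Tensor, hw: tuple[int, int]) -> Tensor:
        H, W = hw
        B, N, C = tokens.shape
        if N != H * W:
            raise ConfigurationError(f"token count {N} != H*W = {H * W}")
        a = self.norm1(tokens).reshape(B, H, W, C)
        a = self.attn(a).reshape(B, N, C)
        tokens = tokens + a
        return tokens + self.ffn(self.norm2(tokens), hw)


class OverlapPatchEmbed(Module):
    """Overlapping 4× patch embedding (7×7 convolution, stride 4, pad 3)."""

    def __init__(self, in_ch: int, dim: int, rng=None):
        super().__init__()
        self.proj = Conv2d(in_ch, dim, kernel=7, stride=4, padding=3, rng=rng)
        self.norm = LayerNorm(dim)

    def forward(self, image: Tensor) -> tuple[Tensor, tuple[int, int]]:
        t = image if isinstance(image, Tensor) else Tensor(image)
        if t.ndim == 3:
            t = t.reshape(t.shape + (1,))
        B, H, W, _ = t.shape
        if H % 4 or W % 4:
            raise ConfigurationError(
                f"image extent {H}x{W} not divisible by 4; pad or resize first"
            )
        x = self.proj(t)
        Ho, Wo = x.shape[1], x.shape[2]
        return self.norm(x.reshape(B, Ho * Wo, x.shape[-1])), (Ho, Wo)


class PatchMerge(Module):
    """Overlapping 2× downsampling (3×3 convolution, stride 2, pad 1) that
    doubles the channel width."""

    def __init__(self, dim: int, out_dim: int | None = None, rng=None):
        super().__init__()
        out_dim = out_dim if out_dim is not None else 2 * dim
        self.proj = Conv2d(dim, out_dim, kernel=3, stride=2, padding=1, rng=rng)
        self.norm = LayerNorm(out_dim)

    def forward(self, tokens: Tensor, hw: tuple[int, int]):
        H, W = hw
        if H % 2 or W % 2:
            raise ConfigurationError(f"cannot merge odd extent {H}x{W}")
        B, N, C = tokens.shape
        x = self.proj(tokens.reshape(B, H, W, C))
        Ho, Wo = x.shape[1], x.shape[2]
        return self.norm(x.reshape(B, Ho * Wo, x.shape[-1])), (Ho, Wo)


def _pixel_shuffle(x: Tensor, r: int) -> Tensor:
    """Channel-to-space rearrangement ``(B,H,W,r²·C) → (B,rH,rW,C)``."""
    B, H, W, C = x.shape
    Co = C // (r * r)
    return (
        x.reshape(B, H, W, r, r, Co)
        .transpose((0, 1, 3, 2, 4, 5))
        .reshape(B, H * r, W * r, Co)
    )


class PatchExpand(Module):
    """2× upsampling by linear width adjustment + channel-to-space shuffle;
    halves the channel width."""

    def __init__(self, dim: int, rng=None):
        super().__init__()
        self.proj = Linear(dim, 2 * dim, rng=rng, bias=False)
        self.norm = LayerNorm(dim // 2)

    def forward(self, tokens: Tensor, hw: tuple[int, int]):
        H, W = hw
        B, N, C = tokens.shape
        x = self.proj(tokens).reshape(B, H, W, 2 * C)
        x = _pixel_shuffle(x, 2)
        return self.norm(x.reshape(B, 4 * N, C // 2)), (2 * H, 2 * W)


class FinalExpandProject(Module):
    """4× upsampling back to pixel resolution + linear projection to class
    logits."""

    def __init__(self, dim: int, num_classes: int, rng=None):
        super().__init__()
        self.proj = Linear(dim, 16 * dim, rng=rng, bias=False)
        self.norm = LayerNorm(dim)
        self.head = Linear(dim, num_classes, rng=rng)

    def forward(self, tokens: Tensor, hw: tuple[int, int]) -> Tensor:
        H, W = hw
        B, N, C = tokens.shape
        x = self.proj(tokens).reshape(B, H, W, 16 * C)
        x = _pixel_shuffle(x, 4)
        x = self.norm(x)
        return self.head(x)  # (B, 4H, 4W, K) logits
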