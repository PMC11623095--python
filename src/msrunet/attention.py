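"""Multi-scale reconfiguration self-attention (MSR-SA).

The operator decomposes dense self-attention into grouped sparse
sub-attentions.  Channels are split into G groups; group *i* tiles the
feature grid into non-overlapping ``S_i × S_i`` windows, samples an
``M × M`` grid of points per window at dilation ``D_i = (S_i - 1)/(M - 1)``,
projects the sampled points to keys/values, and fuses same-position samples
across windows with a symmetric reduction (max by default).  Every query
then attends to exactly ``M²`` fused keys, so each group sees the whole
image at its own granularity for a fixed key budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concat, softmax
from .nn import Linear, Module, Parameter

__all__ = [
    "ConfigurationError",
    "GroupSpec",
    "FUSION_MODES",
    "PRESETS",
    "split_groups",
    "dilation_rate",
    "partition_windows",
    "dilated_sample",
    "fuse_cross_window",
    "group_attention",
    "auto_group_specs",
    "MSRAttention",
]

FUSION_MODES = ("max", "mean", "linear")
PRESETS = ("default", "low", "high")


class ConfigurationError(ValueError):
    """Invalid attention geometry or model configuration."""


@dataclass(frozen=True)
class GroupSpec:
    """Geometry of one attention group.

    Parameters
    ----------
    index : 1-based group number.
    channels : per-group channel width C' = C/G.
    window : window side S (pixels of the feature grid).
    dilation : sampling dilation D; must satisfy S = D*(grid-1) + 1.
    grid : side M of the sampled key grid (M² keys per group; default 7).
    scale : attention scaling h (default: ``channels``, per-head convention).
    """

    index: int
    channels: int
    window: int
    dilation: int
    grid: int = 7
    scale: float | None = None

    @property
    def num_keys(self) -> int:
        return self.grid * self.grid

    @property
    def scaling(self) -> float:
        return float(self.channels if self.scale is None else self.scale)

    def window_count(self, H: int, W: int) -> int:
        return math.ceil(H / self.window) * math.ceil(W / self.window)

    def validate(self, H: int, W: int) -> None:
        if self.channels < 1:
            raise ConfigurationError(f"group {self.index}: channels must be >= 1")
        if self.grid < 1:
            raise ConfigurationError(f"group {self.index}: grid side must be >= 1")
        if self.dilation < 1:
            raise ConfigurationError(f"group {self.index}: dilation must be >= 1")
        expected = self.dilation * (self.grid - 1) + 1
        if self.window != expected:
            raise ConfigurationError(
                f"group {self.index}: window {self.window} != "
                f"D*(M-1)+1 = {expected} (D={self.dilation}, M={self.grid})"
            )
        if self.window > min(H, W):
            raise ConfigurationError(
                f"group {self.index}: window {self.window} exceeds map side "
                f"min({H}, {W})"
            )


def split_groups(x, G: int):
    """Split the channel (last) axis into ``G`` equal groups.

    Concatenating the outputs along channels recovers the input exactly.
    """
    t = x if isinstance(x, Tensor) else Tensor(x)
    C = t.shape[-1]
    if G < 1 or C % G != 0:
        raise ConfigurationError(f"channels C={C} not divisible by G={G} groups")
    Cp = C // G
    sl = [slice(None)] * (t.ndim - 1)
    return [t[tuple(sl + [slice(g * Cp, (g + 1) * Cp)])] for g in range(G)]


def dilation_rate(S: int, M: int) -> int:
    """Dilation D = (S-1)/(M-1) pairing a window side with the sample grid."""
    if M < 2 or S < M:
        raise ConfigurationError(f"need S >= M >= 2, got S={S}, M={M}")
    if (S - 1) % (M - 1) != 0:
        raise ConfigurationError(
            f"invalid window/grid pairing: (S-1)={S - 1} not divisible by (M-1)={M - 1}"
        )
    return (S - 1) // (M - 1)


def partition_windows(xg, S: int):
    """Tile ``(B, H, W, C')`` into non-overlapping ``S×S`` windows.

    The grid is zero-padded on the bottom/right to the next multiple of S.

    Returns
    -------
    windows : Tensor ``(B, M_i, S, S, C')`` with ``M_i = ceil(H/S)*ceil(W/S)``.
    pad : ``(pad_h, pad_w)`` record allowing exact restoration.
    valid : bool array ``(M_i, S, S)`` flagging unpadded positions.
    """
    t = xg if isinstance(xg, Tensor) else Tensor(xg)
    squeeze = t.ndim == 3
    if squeeze:
        t = t.reshape((1,) + t.shape)
    B, H, W, C = t.shape
    if S < 1:
        raise ConfigurationError(f"window side must be >= 1, got {S}")
    nh, nw = math.ceil(H / S), math.ceil(W / S)
    pad_h, pad_w = nh * S - H, nw * S - W
    if pad_h or pad_w:
        t = t.pad(((0, 0), (0, pad_h), (0, pad_w), (0, 0)))
    win = (
        t.reshape(B, nh, S, nw, S, C)
        .transpose((0, 1, 3, 2, 4, 5))
        .reshape(B, nh * nw, S, S, C)
    )
    ones = np.zeros((nh * S, nw * S), dtype=bool)
    ones[:H, :W] = True
    valid = (
        ones.reshape(nh, S, nw, S).transpose(0, 2, 1, 3).reshape(nh * nw, S, S)
    )
    if squeeze:
        win = win.reshape(win.shape[1:])
    return win, (pad_h, pad_w), valid


def unpartition_windows(windows, H: int, W: int):
    """Inverse of :func:`partition_windows`; crops padding back off."""
    t = windows if isinstance(windows, Tensor) else Tensor(windows)
    squeeze = t.ndim == 4
    if squeeze:
        t = t.reshape((1,) + t.shape)
    B, Mi, S, _, C = t.shape
    nh, nw = math.ceil(H / S), math.ceil(W / S)
    grid = (
        t.reshape(B, nh, nw, S, S, C)
        .transpose((0, 1, 3, 2, 4, 5))
        .reshape(B, nh * S, nw * S, C)
    )
    out = grid[:, :H, :W, :]
    if squeeze:
        out = out.reshape(out.shape[1:])
    return out


def dilated_sample(window, M: int, D: int):
    """Sample an ``M×M`` point grid at stride ``D`` from ``(..., S, S, C')``.

    Sampled row/col indices are ``{0, D, 2D, ..., (M-1)D}`` anchored at the
    window origin; requires ``D*(M-1)+1 == S``.
    """
    t = window if isinstance(window, Tensor) else Tensor(window)
    S = t.shape[-2]
    if t.shape[-3] != S:
        raise ConfigurationError(f"windows must be square, got {t.shape[-3]}x{S}")
    if D * (M - 1) + 1 != S:
        raise ConfigurationError(
            f"inconsistent (S, M, D) = ({S}, {M}, {D}): D*(M-1)+1 = {D * (M - 1) + 1}"
        )
    idx = tuple([slice(None)] * (t.ndim - 3) + [slice(0, S, D), slice(0, S, D), slice(None)])
    return t[idx]


def sample_valid_mask(valid: np.ndarray, M: int, D: int) -> np.ndarray:
    """Apply the dilated-sampling pattern to a window validity mask."""
    return valid[:, ::D, ::D].reshape(valid.shape[0], M * M)


def fuse_cross_window(per_window, mode: str, valid=None, weights=None):
    """Reduce the window axis of ``(..., M_i, L, C')`` sampled features.

    ``max``/``mean`` are symmetric in window order; ``linear`` is a learnable
    weighted sum (``weights`` of length ``M_i`` required).  Positions flagged
    invalid (bottom/right padding) are excluded from the reduction.
    """
    t = per_window if isinstance(per_window, Tensor) else Tensor(per_window)
    if mode not in FUSION_MODES:
        raise ConfigurationError(
            f"unknown fusion mode {mode!r}; valid modes: {FUSION_MODES}"
        )
    axis = t.ndim - 3
    Mi = t.shape[axis]
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        if valid.shape != (Mi, t.shape[-2]):
            raise ConfigurationError(
                f"validity mask shape {valid.shape} != {(Mi, t.shape[-2])}"
            )
    if mode == "max":
        if valid is not None and not valid.all():
            penalty = np.where(valid, 0.0, -1e30)[..., None]
            t = t + Tensor(penalty)
        return t.max(axis=axis)
    if mode == "mean":
        return _window_mean(t, axis, valid)
    # linear
    if weights is None:
        raise ConfigurationError("linear fusion requires a weight vector")
    w = weights if isinstance(weights, Tensor) else Tensor(weights)
    if w.shape != (Mi,):
        raise ConfigurationError(f"linear fusion weights shape {w.shape} != ({Mi},)")
    w = w.reshape(Mi, 1, 1)
    if valid is not None and not valid.all():
        w = w * Tensor(valid.astype(np.float64)[..., None])
    return (t * w).sum(axis=axis)


def _window_mean(t: Tensor, axis: int, valid) -> Tensor:
    """Mean over the window axis, summed in sorted order so the result is
    bitwise invariant to window permutation (a mean's gradient is uniform,
    so sorting does not complicate the backward pass)."""
    xd = t.data
    if valid is None or bool(valid.all()):
        mask = None
        cnt = float(xd.shape[axis])
        out = np.sort(xd, axis=axis).sum(axis=axis) / cnt
    else:
        mask = valid.astype(xd.dtype)[..., None]
        cnt = mask.sum(axis=0)  # (L, 1); >= 1 by the padding policy
        out = np.sort(xd * mask, axis=axis).sum(axis=axis) / cnt

    def backward(g):
        if not t.requires_grad:
            return
        gi = np.expand_dims(g / cnt, axis)
        if mask is not None:
            gi = gi * mask
        t._accum(np.broadcast_to(gi, xd.shape).copy())

    return Tensor._make(out, (t,), backward)


def group_attention(Q, K, V, h: float):
    """Scaled dot-product attention ``softmax(Q Kᵀ / sqrt(h)) V``."""
    Qt = Q if isinstance(Q, Tensor) else Tensor(Q)
    Kt = K if isinstance(K, Tensor) else Tensor(K)
    Vt = V if isinstance(V, Tensor) else Tensor(V)
    if h <= 0:
        raise ConfigurationError(f"scaling factor must be positive, got {h}")
    if Qt.shape[-1] != Kt.shape[-1] or Kt.shape != Vt.shape:
        raise ConfigurationError(
            f"dimension mismatch: Q{Qt.shape} K{Kt.shape} V{Vt.shape}"
        )
    swap = tuple(range(Kt.ndim - 2)) + (Kt.ndim - 1, Kt.ndim - 2)
    scores = (Qt @ Kt.transpose(swap)) * (1.0 / math.sqrt(h))
    return softmax(scores, axis=-1) @ Vt


def auto_group_specs(
    H: int,
    W: int,
    C: int,
    G: int,
    preset: str = "default",
    grid: int = 7,
) -> list[GroupSpec]:
    """Build per-group specs for a feature map, clamped to its geometry.

    ``default`` doubles the dilation per group (1, 2, 4, ...); ``low`` keeps
    every dilation at 1 (single-scale windows); ``high`` gives every group
    the largest valid window not exceeding the map side.  On maps smaller
    than the sampling grid the grid side is clamped to the map side, which
    degenerates to dense attention.
    """
    if preset not in PRESETS:
        raise ConfigurationError(f"unknown preset {preset!r}; valid: {PRESETS}")
    if G < 1 or C % G != 0:
        raise ConfigurationError(f"channels C={C} not divisible by G={G} groups")
    side = min(H, W)
    M = min(grid, side)
    d_max = (side - 1) // (M - 1) if M > 1 else 1
    specs = []
    for i in range(1, G + 1):
        if preset == "low":
            D = 1
        elif preset == "high":
            D = d_max
        else:
            D = min(2 ** (i - 1), d_max)
        specs.append(
            GroupSpec(index=i, channels=C // G, window=D * (M - 1) + 1, dilation=D, grid=M)
        )
    return specs


class MSRAttention(Module):
    """The MSR-SA operator as a layer: grouped, dilated, cross-window-fused
    self-attention with per-group 1×1 query/key/value projections.

    Output shape equals input shape ``(B, H, W, C)``; each group attends to
    exactly ``M²`` fused keys whatever its window size.
    """

    def __init__(
        self,
        channels: int,
        specs: list[GroupSpec],
        fusion: str = "max",
        rng: np.random.Generator | None = None,
        grid_hw: tuple[int, int] | None = None,
        init: str = "trunc_normal",
    ):
        super().__init__()
        if fusion not in FUSION_MODES:
            raise ConfigurationError(
                f"unknown fusion mode {fusion!r}; valid modes: {FUSION_MODES}"
            )
        Cp = specs[0].channels
        if any(s.channels != Cp for s in specs) or Cp * len(specs) != channels:
            raise ConfigurationError(
                f"group channels {[s.channels for s in specs]} do not tile C={channels}"
            )
        self.channels = channels
        self.specs = list(specs)
        self.fusion = fusion
        self.q_proj = [Linear(Cp, Cp, rng=rng) for _ in specs]
        self.k_proj = [Linear(Cp, Cp, rng=rng) for _ in specs]
        self.v_proj = [Linear(Cp, Cp, rng=rng) for _ in specs]
        if init == "identity":
            for lin in (*self.q_proj, *self.k_proj, *self.v_proj):
                lin.weight.data = np.eye(Cp)
        elif init != "trunc_normal":
            raise ConfigurationError(f"unknown init {init!r}")
        self.fuse_weights: list[Parameter] | None = None
        if fusion == "linear":
            if grid_hw is None:
                raise ConfigurationError(
                    "linear fusion needs grid_hw=(H, W) to size its window weights"
                )
            self.fuse_weights = [
                Parameter(np.full(s.window_count(*grid_hw), 1.0 / s.window_count(*grid_hw)))
                for s in specs
            ]

    def forward(self, x: Tensor) -> Tensor:
        t = x if isinstance(x, Tensor) else Tensor(x)
        B, H, W, C = t.shape
        if C != self.channels:
            raise ConfigurationError(f"input has C={C}, layer expects {self.channels}")
        for s in self.specs:
            s.validate(H, W)
        groups = split_groups(t, len(self.specs))
        outs = []
        for g, (xg, spec) in enumerate(zip(groups, self.specs)):
            Cp, S, M, D = spec.channels, spec.window, spec.grid, spec.dilation
            q = self.q_proj[g](xg.reshape(B, H * W, Cp))
            windows, _, valid = partition_windows(xg, S)
            pts = dilated_sample(windows, M, D)
            pts = pts.reshape(B, windows.shape[1], M * M, Cp)
            vmask = sample_valid_mask(valid, M, D)
            fw = self.fuse_weights[g] if self.fuse_weights is not None else None
            k = fuse_cross_window(self.k_proj[g](pts), self.fusion, vmask, fw)
            v = fuse_cross_window(self.v_proj[g](pts), self.fusion, vmask, fw)
            attended = group_attention(q, k, v, spec.scaling)
            outs.append(attended.reshape(B, H, W, Cp))
        return concat(outs, axis=-1)
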