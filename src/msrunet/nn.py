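"""Neural-network building blocks on top of :mod:`msrunet.autograd`.

Layers follow a channels-last convention: token sequences are ``(B, N, C)``
and spatial grids ``(B, H, W, C)``.  Convolutions are expressed as sums of
strided slices times kernel-position weights, which keeps them inside the
autodiff graph without a dedicated im2col kernel.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autograd import Tensor, layer_norm, no_grad

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "LayerNorm",
    "Conv2d",
    "DepthwiseConv2d",
    "SGD",
    "trunc_normal",
]


def trunc_normal(
    shape: tuple, std: float = 0.02, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Truncated-normal sample (cut at ±2 std, the usual transformer init)."""
    rng = rng or np.random.default_rng()
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2.0 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2.0 * std
    return x


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters require grad even under no_grad


class Module:
    """Tiny module system: tracks parameters and sub-modules by attribute."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.copy()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def astype(self, dtype) -> "Module":
        """Cast all parameters in place (e.g. float32 for training runs)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng=None, bias: bool = True):
        super().__init__()
        self.weight = Parameter(trunc_normal((in_dim, out_dim), rng=rng))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class Conv2d(Module):
    """2D convolution on ``(B, H, W, Cin)`` grids, weight ``(kh, kw, Cin, Cout)``.

    Realized as a sum over kernel positions of strided slices matmul'd with
    the per-position weight — exact, autodiff-friendly, and fast enough for
    the small kernels used here.
    """

    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, rng=None):
        super().__init__()
        fan_in = kernel * kernel * in_ch
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            trunc_normal((kernel, kernel, in_ch, out_ch), std=std, rng=rng)
        )
        self.bias = Parameter(np.zeros(out_ch))
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel, self.stride, self.padding
        t = x if isinstance(x, Tensor) else Tensor(x)
        w, b = self.weight, self.bias
        B, H, W, C = t.shape
        xp = np.pad(t.data, ((0, 0), (p, p), (p, p), (0, 0))) if p else t.data
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        # im2col: (B, Ho, Wo, k, k, C) -> one matmul with (k*k*C, Cout)
        sw = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        cols = np.ascontiguousarray(
            sw[:, ::s, ::s].transpose(0, 1, 2, 4, 5, 3)
        ).reshape(B, Ho, Wo, k * k * C)
        wmat = w.data.reshape(k * k * C, -1)
        out = cols @ wmat + b.data

        def backward(g):
            if w.requires_grad:
                gw = cols.reshape(-1, k * k * C).T @ g.reshape(-1, g.shape[-1])
                w._accum(gw.reshape(w.data.shape))
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 1, 2)))
            if t.requires_grad:
                gcols = (g @ wmat.T).reshape(B, Ho, Wo, k, k, C)
                gxp = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        gxp[
                            :,
                            i : i + (Ho - 1) * s + 1 : s,
                            j : j + (Wo - 1) * s + 1 : s,
                            :,
                        ] += gcols[:, :, :, i, j, :]
                t._accum(gxp[:, p : p + H, p : p + W, :] if p else gxp)

        return Tensor._make(out, (t, w, b), backward)


class DepthwiseConv2d(Module):
    """3x3 depthwise convolution (stride 1, same padding) on ``(B,H,W,C)``."""

    def __init__(self, dim: int, kernel: int = 3, rng=None):
        super().__init__()
        std = math.sqrt(2.0 / (kernel * kernel))
        self.weight = Parameter(trunc_normal((kernel, kernel, dim), std=std, rng=rng))
        self.bias = Parameter(np.zeros(dim))
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        k = self.kernel
        p = k // 2
        t = x if isinstance(x, Tensor) else Tensor(x)
        w, b = self.weight, self.bias
        B, H, W, C = t.shape
        xp = np.pad(t.data, ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.broadcast_to(b.data, (B, H, W, C)).copy()
        for i in range(k):
            for j in range(k):
                out += xp[:, i : i + H, j : j + W, :] * w.data[i, j]

        def backward(g):
            if w.requires_grad:
                gw = np.empty_like(w.data)
                for i in range(k):
                    for j in range(k):
                        gw[i, j] = np.einsum(
                            "bhwc,bhwc->c", g, xp[:, i : i + H, j : j + W, :]
                        )
                w._accum(gw)
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 1, 2)))
            if t.requires_grad:
                gxp = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        gxp[:, i : i + H, j : j + W, :] += g * w.data[i, j]
                t._accum(gxp[:, p : p + H, p : p + W, :])

        return Tensor._make(out, (t, w, b), backward)


class SGD:
    """Stochastic gradient descent with momentum and decoupled weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        with no_grad():
            for p, v in zip(self.params, self._velocity):
                if p.grad is None:
                    continue
                g = p.grad + self.weight_decay * p.data
                v *= self.momentum
                v += g
                p.data -= (self.lr * v).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
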