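"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float64 ``ndarray`` and records the operations
applied to it; :meth:`Tensor.backward` accumulates gradients through the
recorded graph.  Only the operations needed by the segmentation network are
provided (elementwise arithmetic, matmul, reshape/transpose/slicing,
padding, concatenation, reductions with max/mean, exp/log/tanh/erf-GELU,
softmax).  Everything runs on CPU and is deterministic.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy import special as _sp_special

__all__ = [
    "Tensor",
    "concat",
    "softmax",
    "layer_norm",
    "no_grad",
    "is_grad_enabled",
    "default_dtype",
    "get_default_dtype",
]

_GRAD_ENABLED = [True]
_DTYPE = [np.float64]


class default_dtype:
    """Context manager setting the dtype of newly created tensors.

    float64 is the default; float32 halves memory traffic for training runs
    where round-off at 1e-7 is irrelevant.
    """

    def __init__(self, dtype):
        self._dtype = np.dtype(dtype).type

    def __enter__(self):
        self._prev = _DTYPE[0]
        _DTYPE[0] = self._dtype
        return self

    def __exit__(self, *exc):
        _DTYPE[0] = self._prev
        return False


def get_default_dtype():
    return _DTYPE[0]


class no_grad:
    """Context manager disabling graph recording (inference / optimizer steps)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[0]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        return x.data
    return np.asarray(x, dtype=_DTYPE[0])


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "_grad_owned")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE[0])
        self.grad: np.ndarray | None = None
        self._grad_owned = False
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED[0]
        self._backward = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = _GRAD_ENABLED[0] and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=False)
        out.requires_grad = req
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        # first contribution is stored by reference (it may be a view we do
        # not own); later contributions materialize an owned buffer once
        if self.grad is None:
            self.grad = grad
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += grad
        else:
            self.grad = self.grad + grad
            self._grad_owned = True

    def backward(self, grad=None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        # iterative topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        out_data = self.data + o.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g, o.data.shape))

        return Tensor._make(out_data, (self, o), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        out_data = self.data - o.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(-g, o.data.shape))

        return Tensor._make(out_data, (self, o), backward)

    def __rsub__(self, other):
        return Tensor(_as_array(other)) - self

    def __mul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        out_data = self.data * o.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * o.data, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * self.data, o.data.shape))

        return Tensor._make(out_data, (self, o), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        out_data = self.data / o.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / o.data, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(-g * self.data / (o.data * o.data), o.data.shape))

        return Tensor._make(out_data, (self, o), backward)

    def __rtruediv__(self, other):
        return Tensor(_as_array(other)) / self

    def __pow__(self, exponent: float):
        p = float(exponent)
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        out_data = self.data @ o.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(o.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if o.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                o._accum(_unbroadcast(gb, o.data.shape))

        return Tensor._make(out_data, (self, o), backward)

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data * out_data))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def gelu(self):
        """Exact GELU, x * Phi(x), with analytic gradient."""
        x = self.data
        cdf = 0.5 * (1.0 + _sp_special.erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (cdf + x * pdf))

        return Tensor._make(x * cdf, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is zero where the clamp is active."""
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    # -------------------------------------------------------------- shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def backward(g):
            if self.requires_grad:
                self._accum(np.transpose(g, inv))

        return Tensor._make(np.transpose(self.data, axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.data.shape
        # basic indexing (ints/slices) selects distinct elements, so the
        # scatter in the backward pass can use a plain in-place add
        basic = isinstance(idx, (int, slice)) or (
            isinstance(idx, tuple)
            and all(isinstance(i, (int, slice)) for i in idx)
        )

        def backward(g):
            if self.requires_grad:
                gx = np.zeros(shape, dtype=g.dtype)
                if basic:
                    gx[idx] += g
                else:
                    np.add.at(gx, idx, g)
                self._accum(gx)

        return Tensor._make(out_data, (self,), backward)

    def pad(self, pad_width):
        """Zero padding; ``pad_width`` as for :func:`numpy.pad`."""
        pw = tuple((int(a), int(b)) for a, b in pad_width)
        out_data = np.pad(self.data, pw)
        slices = tuple(slice(a, a + s) for (a, _), s in zip(pw, self.data.shape))

        def backward(g):
            if self.requires_grad:
                self._accum(g[slices])

        return Tensor._make(out_data, (self,), backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; ties route the gradient to the first maximum."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        idx = np.argmax(self.data, axis=axis)
        shape = self.data.shape

        def backward(g):
            if not self.requires_grad:
                return
            gx = np.zeros(shape, dtype=g.dtype)
            gr = g if keepdims else np.expand_dims(g, axis)
            np.put_along_axis(
                gx, np.expand_dims(idx, axis), gr, axis=axis
            )
            self._accum(gx)

        return Tensor._make(out_data, (self,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(int(a), int(b))
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, ts, backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` (fused primitive)."""
    t = x if isinstance(x, Tensor) else Tensor(x)
    z = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if t.requires_grad:
            gy = g * y
            t._accum(gy - y * gy.sum(axis=axis, keepdims=True))

    return Tensor._make(y, (t,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalization over the last axis (fused primitive)."""
    t = x if isinstance(x, Tensor) else Tensor(x)
    mu = t.data.mean(axis=-1, keepdims=True)
    xc = t.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xn = xc * inv
    out = xn * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad:
            red = tuple(range(g.ndim - 1))
            gamma._accum((g * xn).sum(axis=red))
        if beta.requires_grad:
            red = tuple(range(g.ndim - 1))
            beta._accum(g.sum(axis=red))
        if t.requires_grad:
            gn = g * gamma.data
            t._accum(
                inv
                * (
                    gn
                    - gn.mean(axis=-1, keepdims=True)
                    - xn * (gn * xn).mean(axis=-1, keepdims=True)
                )
            )

    return Tensor._make(out, (t, gamma, beta), backward)
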