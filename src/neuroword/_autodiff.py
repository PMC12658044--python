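"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the decoding network needs: broadcasted
arithmetic, (batched) matmul, reductions, elementwise nonlinearities,
shape manipulation, indexing and concatenation.  Gradients are accumulated
through a topologically-ordered tape; all ops are numerically checked
against central differences in the test suite.

Not a general framework: no in-place ops, no higher-order gradients.
"""

from __future__ import annotations

import contextlib
import ctypes
import sys
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "no_grad", "concat", "stack"]

_GRAD_ENABLED = True


def _tune_allocator() -> None:
    """Keep large freed buffers on the heap for reuse.

    Training allocates and frees many multi-MB arrays per step; glibc serves
    those via mmap/munmap by default, so every step pays page faults for the
    whole graph again.  Routing them through the (untrimmed) heap lets the
    next step reuse the same pages.
    """
    if not sys.platform.startswith("linux"):
        return
    try:
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-4, 0)        # M_MMAP_MAX = 0
        libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
    except Exception:  # pragma: no cover - best effort
        pass


_tune_allocator()


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(x, requires_grad=False)


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_owned")
    __array_priority__ = 100  # make numpy defer to our __radd__ etc.

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype.kind != "f":
            data = data.astype(np.float64)
        self.data = data  # dtype is preserved (float32 or float64)
        self.grad: np.ndarray | None = None
        self._grad_owned = False
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helper -------------------------------------------------
    @staticmethod
    def _from_op(data: np.ndarray, parents: Sequence["Tensor"],
                 backward: Callable[[np.ndarray], None]) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic protocol ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = _as_tensor(other)
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._from_op(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            self._accumulate(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other)
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._from_op(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = _as_tensor(other)
        data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor._from_op(data, (self, other), backward)

    def __rtruediv__(self, other) -> "Tensor":
        return _as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        data = self.data**exponent

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._from_op(data, (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = _as_tensor(other)
        a, b = self.data, other.data
        # stacked @ 2-D collapses to one large GEMM (much faster than the
        # batched loop, and its weight gradient needs no (batch, k, n) buffer)
        flat = a.ndim > 2 and b.ndim == 2
        if flat:
            data = (a.reshape(-1, a.shape[-1]) @ b).reshape(
                *a.shape[:-1], b.shape[-1])
        else:
            data = a @ b

        def backward(g):
            if flat:
                g2 = g.reshape(-1, b.shape[-1])
                if self.requires_grad:
                    self._accumulate((g2 @ b.T).reshape(a.shape))
                if other.requires_grad:
                    other._accumulate(a.reshape(-1, a.shape[-1]).T @ g2)
                return
            if self.requires_grad:
                ga = g @ np.swapaxes(b, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(a, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor._from_op(data, (self, other), backward)

    # -- elementwise ---------------------------------------------------------
    def exp(self) -> "Tensor":
        data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * data)

        return Tensor._from_op(data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def tanh(self) -> "Tensor":
        data = np.tanh(self.data)

        def backward(g):
            self._accumulate(g * (1.0 - data**2))

        return Tensor._from_op(data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward(g):
            self._accumulate(g * data * (1.0 - data))

        return Tensor._from_op(data, (self,), backward)

    def log_sigmoid(self) -> "Tensor":
        # log sigma(x) = -softplus(-x), computed stably
        x = self.data
        data = np.where(x > 0, -np.log1p(np.exp(-np.abs(x))),
                        x - np.log1p(np.exp(-np.abs(x))))
        sig = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))

        def backward(g):
            self._accumulate(g * (1.0 - sig))

        return Tensor._from_op(data, (self,), backward)

    def gelu(self) -> "Tensor":
        # tanh approximation of GELU, buffer-frugal (hot path in the conv net)
        x = self.data
        c = np.float64(np.sqrt(2.0 / np.pi)).astype(x.dtype)
        t = x * x
        t *= np.asarray(0.044715, dtype=x.dtype)
        t += 1.0
        t *= x
        t *= c
        np.tanh(t, out=t)  # t = tanh(c (x + 0.044715 x^3)), kept for backward
        data = t + 1.0
        data *= x
        data *= 0.5

        def backward(g):
            di = x * x
            di *= np.asarray(3 * 0.044715, dtype=x.dtype)
            di += 1.0
            di *= c                       # d(inner)/dx
            sech2 = 1.0 - t * t
            di *= sech2
            di *= x
            di += 1.0
            di += t                        # = (1+t) + x (1-t^2) inner'
            di *= 0.5
            di *= g
            self._accumulate(di)

        return Tensor._from_op(data, (self,), backward)

    def sqrt(self) -> "Tensor":
        return self**0.5

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._from_op(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            full = data
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
                full = np.expand_dims(data, axis)
            mask = (self.data == full).astype(self.data.dtype)
            mask /= mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
            self._accumulate(mask * g)

        return Tensor._from_op(data, (self,), backward)

    # -- shape ---------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        data = self.data.reshape(shape)
        orig = self.shape

        def backward(g):
            self._accumulate(g.reshape(orig))

        return Tensor._from_op(data, (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return Tensor._from_op(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, idx) -> "Tensor":
        data = self.data[idx]
        orig_shape = self.shape
        items = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(i, (int, np.integer, slice)) or i is Ellipsis
                    or i is None for i in items)

        def backward(g):
            full = np.zeros(orig_shape, dtype=self.data.dtype)
            if basic:  # no repeated positions possible: plain assignment
                full[idx] = g
            else:      # fancy indexing may repeat entries
                np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor._from_op(data, (self,), backward)

    # -- softmax (stable, fused) ----------------------------------------------
    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * data).sum(axis=axis, keepdims=True)
            self._accumulate(data * (g - dot))

        return Tensor._from_op(data, (self,), backward)

    def log_softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        data = shifted - lse
        soft = np.exp(data)

        def backward(g):
            self._accumulate(g - soft * g.sum(axis=axis, keepdims=True))

        return Tensor._from_op(data, (self,), backward)

    # -- backward ------------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        g = np.asarray(g)
        if g.dtype != self.data.dtype:
            g = g.astype(self.data.dtype)
        if self.grad is None:
            # adopt without copying; the array may be shared with a sibling,
            # so it is copied lazily before any in-place update
            self.grad = g
            self._grad_owned = False
        else:
            if not self._grad_owned:
                self.grad = self.grad.copy()
                self._grad_owned = True
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads/graph to bound memory
                if not isinstance(node, Parameter):
                    node.grad = None
                node._backward = None
                node._parents = ()


class Parameter(Tensor):
    """A trainable leaf tensor."""

    __slots__ = ("name",)

    def __init__(self, data, name: str = ""):
        # parameters are trainable regardless of the no_grad state at
        # construction time
        super().__init__(np.array(data), requires_grad=False)
        self.requires_grad = True
        self.name = name

    def zero_grad(self) -> None:
        self.grad = None
        self._grad_owned = False


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else _as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._from_op(data, tensors, backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else _as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        parts = np.moveaxis(g, axis, 0)
        for t, gp in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(gp)

    return Tensor._from_op(data, tensors, backward)
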