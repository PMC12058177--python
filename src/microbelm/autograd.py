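"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations a transformer encoder needs: broadcasting
arithmetic, (batched) matrix products, reductions, softmax, layer
normalization, embedding lookup, dropout and the usual pointwise
nonlinearities.  Gradients are accumulated on a dynamically built tape and
released after :meth:`Tensor.backward`.
"""

from __future__ import annotations

import contextlib
import gc
from typing import Callable, Iterable

import numpy as np

_grad_enabled: bool = True


def _tune_allocator() -> None:
    """Keep large freed buffers on the heap instead of returning them to the
    kernel.  Training holds many ~1-10 MB activation arrays on the tape; with
    glibc defaults each one is mmap'd and munmap'd individually, so every
    batch repays the page-fault cost of its whole working set.  Raising the
    mmap/trim thresholds lets steady-state batches recycle already-faulted
    pages.  Best-effort: silently skipped off glibc."""
    try:
        import ctypes

        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-3, 64 * 1024 * 1024)  # M_MMAP_THRESHOLD
        libc.mallopt(-1, 256 * 1024 * 1024)  # M_TRIM_THRESHOLD
    except Exception:
        pass


_tune_allocator()


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


@contextlib.contextmanager
def tape_arena():
    """Pause the cyclic garbage collector while a tape is being built.

    The autodiff graph is an acyclic structure of closures and tuples that
    reference counting alone reclaims; leaving the cyclic collector running
    makes it rescan the growing tape on every allocation burst, which
    dominates runtime.  Training and batched-inference loops wrap their
    hot sections in this context.
    """
    was_enabled = gc.isenabled()
    gc.disable()
    try:
        yield
    finally:
        if was_enabled:
            gc.enable()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _grad_enabled
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- bookkeeping ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # freshly computed contribution; safe to take by reference
            self.grad = grad if grad.dtype == self.data.dtype else grad.astype(self.data.dtype)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=self.dtype)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, self.dtype))
        out_data = self.data + other.data
        req = self.requires_grad or other.requires_grad
        out = Tensor(out_data, req, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, self.dtype))
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, self.dtype))
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(np.asarray(other, self.dtype)) + (-self)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other.pow(-1.0)
        return self * (1.0 / other)

    def pow(self, exponent: float):
        out = Tensor(self.data**exponent, self.requires_grad, (self,))

        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bw if out.requires_grad else None
        return out

    def __matmul__(self, other: "Tensor"):
        out = Tensor(self.data @ other.data, self.requires_grad or other.requires_grad, (self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = bw if out.requires_grad else None
        return out

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def bw(g):
            self._accumulate(g.reshape(self.shape))

        out._backward = bw if out.requires_grad else None
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), self.requires_grad, (self,))

        def bw(g):
            self._accumulate(np.swapaxes(g, a, b))

        out._backward = bw if out.requires_grad else None
        return out

    def select(self, index) -> "Tensor":
        """Basic/advanced indexing with scatter-add backward."""
        out = Tensor(self.data[index], self.requires_grad, (self,))
        basic = all(isinstance(i, (int, slice)) for i in index) if isinstance(
            index, tuple) else isinstance(index, (int, slice))

        def bw(g):
            full = np.zeros_like(self.data)
            if basic:  # no repeated positions: plain in-place add
                full[index] += g
            else:
                np.add.at(full, index, g)
            self._accumulate(full)

        out._backward = bw if out.requires_grad else None
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bw if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- pointwise nonlinearities ---------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def bw(g):
            self._accumulate(g * mask)

        out._backward = bw if out.requires_grad else None
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,))

        def bw(g):
            self._accumulate(g * e)

        out._backward = bw if out.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bw(g):
            self._accumulate(g / self.data)

        out._backward = bw if out.requires_grad else None
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))

        def bw(g):
            self._accumulate(g * s * (1.0 - s))

        out._backward = bw if out.requires_grad else None
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, self.requires_grad, (self,))

        def bw(g):
            self._accumulate(g * (1.0 - t * t))

        out._backward = bw if out.requires_grad else None
        return out


# -- composite / fused operations ---------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, x.requires_grad, (x,))

    def bw(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))

    out._backward = bw if out.requires_grad else None
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data
    req = x.requires_grad or gamma.requires_grad or beta.requires_grad
    out = Tensor(out_data, req, (x, gamma, beta))

    def bw(g):
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            d = x.shape[-1]
            gx = g * gamma.data
            term1 = gx
            term2 = gx.mean(axis=-1, keepdims=True)
            term3 = xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv * (term1 - term2 - term3))

    out._backward = bw if out.requires_grad else None
    return out


def embedding(weight: Tensor, indices: np.ndarray, frozen_rows: np.ndarray | None = None) -> Tensor:
    """Row gather with scatter-add backward; ``frozen_rows`` never receive grad."""
    idx = np.asarray(indices)
    out = Tensor(weight.data[idx], weight.requires_grad, (weight,))

    def bw(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, idx, g)
        if frozen_rows is not None:
            full[frozen_rows] = 0.0
        weight._accumulate(full)

    out._backward = bw if out.requires_grad else None
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    draw = rng.random(x.shape, dtype=np.float32)
    keep = (draw >= p).astype(x.dtype) / (1.0 - p)
    return x * Tensor(keep)


def cross_entropy_logits(logits: Tensor, targets: np.ndarray, weights: np.ndarray) -> Tensor:
    """Mean weighted cross-entropy over arbitrary leading axes.

    ``logits``: (..., V); ``targets``: integer array (...,); ``weights``:
    float array (...,) — positions with weight 0 (PAD, unmasked) do not
    contribute.  Returns a scalar tensor.
    """
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    flat_t = np.asarray(targets)
    nll = -np.take_along_axis(logp, flat_t[..., None], axis=-1)[..., 0]
    w = np.asarray(weights, dtype=logits.dtype)
    total = w.sum()
    loss_val = (nll * w).sum() / max(total, 1.0)
    out = Tensor(np.asarray(loss_val, dtype=logits.dtype), logits.requires_grad, (logits,))

    def bw(g):
        p = np.exp(logp)
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, flat_t[..., None], 1.0, axis=-1)
        grad = (p - onehot) * (w / max(total, 1.0))[..., None]
        logits._accumulate(g * grad)

    out._backward = bw if out.requires_grad else None
    return out


def bce_logits(logits: Tensor, labels: np.ndarray, weights: np.ndarray | None = None) -> Tensor:
    """Mean (weighted) binary cross-entropy from raw logits; numerically stable."""
    x = logits.data
    y = np.asarray(labels, dtype=x.dtype)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=x.dtype)
    total = w.sum()
    per = np.maximum(x, 0) - x * y + np.log1p(np.exp(-np.abs(x)))
    out = Tensor(np.asarray((per * w).sum() / max(total, 1.0), dtype=x.dtype),
                 logits.requires_grad, (logits,))

    def bw(g):
        s = 1.0 / (1.0 + np.exp(-x))
        logits._accumulate(g * (s - y) * w / max(total, 1.0))

    out._backward = bw if out.requires_grad else None
    return out
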