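"""Neural-network building blocks and optimizers on top of :mod:`microbelm.autograd`."""

from __future__ import annotations

import hashlib
from typing import Iterator

import numpy as np

from .autograd import Tensor, dropout, embedding, layer_norm, softmax


class Parameter(Tensor):
    """A named, optionally trainable leaf tensor."""

    __slots__ = ("name", "trainable")

    def __init__(self, data: np.ndarray, name: str, trainable: bool = True):
        super().__init__(np.asarray(data), requires_grad=True)
        self.name = name
        self.trainable = trainable


class Module:
    """Tiny module base: recursive parameter discovery via attributes."""

    def parameters(self) -> Iterator[Parameter]:
        seen: set[int] = set()
        for value in vars(self).values():
            if isinstance(value, Parameter):
                if id(value) not in seen:
                    seen.add(id(value))
                    yield value
            elif isinstance(value, Module):
                yield from value.parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.parameters()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def trainable_parameters(self) -> list[Parameter]:
        return [p for p in self.parameters() if p.trainable]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name!r} in state dict")
            if state[p.name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {p.name!r}")
            p.data = state[p.name].astype(p.data.dtype).copy()

    def checksum(self, names: Iterator[str] | None = None) -> str:
        """SHA-256 over (a subset of) parameter bytes; bit-exact identity probe."""
        h = hashlib.sha256()
        wanted = set(names) if names is not None else None
        for p in sorted(self.parameters(), key=lambda q: q.name):
            if wanted is None or p.name in wanted:
                h.update(p.name.encode())
                h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()


def _init(rng: np.random.Generator, shape, scale: float, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * scale).astype(dtype)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, name: str, dtype=np.float32):
        scale = 1.0 / np.sqrt(d_in)
        self.w = Parameter(_init(rng, (d_in, d_out), scale, dtype), f"{name}.w")
        self.b = Parameter(np.zeros(d_out, dtype=dtype), f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, name: str, dtype=np.float32):
        self.gamma = Parameter(np.ones(dim, dtype=dtype), f"{name}.gamma")
        self.beta = Parameter(np.zeros(dim, dtype=dtype), f"{name}.beta")

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class Embedding(Module):
    """Token embedding with an optional per-row freeze mask.

    Frozen rows never receive gradient, which (with momentum/Adam states
    starting at zero) keeps them bit-identical across any number of
    optimizer steps.
    """

    def __init__(self, weight: np.ndarray, name: str, frozen_rows: np.ndarray | None = None):
        self.weight = Parameter(weight, f"{name}.weight")
        self.frozen_rows = frozen_rows

    def __call__(self, indices: np.ndarray) -> Tensor:
        return embedding(self.weight, indices, self.frozen_rows)


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator, name: str, dtype=np.float32):
        if dim % n_heads:
            raise ValueError("hidden dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng, f"{name}.qkv", dtype)
        self.out = Linear(dim, dim, rng, f"{name}.out", dtype)

    def __call__(self, x: Tensor, attn_bias: np.ndarray) -> Tensor:
        b, s, d = x.shape
        h, dh = self.n_heads, self.d_head
        qkv = self.qkv(x)  # (B,S,3D)
        qkv = qkv.reshape(b, s, 3, h, dh).swapaxes(1, 3)  # (B,H,3,S,dh)
        q = qkv.select((slice(None), slice(None), 0))
        k = qkv.select((slice(None), slice(None), 1))
        v = qkv.select((slice(None), slice(None), 2))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        scores = scores + Tensor(attn_bias)  # (B,1,1,S) additive key mask
        attn = softmax(scores, axis=-1)
        ctx = attn @ v  # (B,H,S,dh)
        ctx = ctx.swapaxes(1, 2).reshape(b, s, d)
        return self.out(ctx)


class FeedForward(Module):
    def __init__(self, dim: int, ff_dim: int, rng: np.random.Generator, name: str, dtype=np.float32):
        self.fc1 = Linear(dim, ff_dim, rng, f"{name}.fc1", dtype)
        self.fc2 = Linear(ff_dim, dim, rng, f"{name}.fc2", dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class EncoderBlock(Module):
    """Post-norm transformer block: LN(x + Attn(x)); LN(x + FF(x))."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int, drop: float,
                 rng: np.random.Generator, name: str, dtype=np.float32):
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng, f"{name}.attn", dtype)
        self.ln1 = LayerNorm(dim, f"{name}.ln1", dtype)
        self.ff = FeedForward(dim, ff_dim, rng, f"{name}.ff", dtype)
        self.ln2 = LayerNorm(dim, f"{name}.ln2", dtype)
        self.drop = drop

    def __call__(self, x: Tensor, attn_bias: np.ndarray, rng: np.random.Generator,
                 training: bool) -> Tensor:
        a = dropout(self.attn(x, attn_bias), self.drop, rng, training)
        x = self.ln1(x + a)
        f = dropout(self.ff(x), self.drop, rng, training)
        return self.ln2(x + f)


class TwoLayerHead(Module):
    """Two-layer feed-forward head (hidden ReLU layer, linear output)."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng: np.random.Generator,
                 name: str, dtype=np.float32):
        self.fc1 = Linear(d_in, d_hidden, rng, f"{name}.fc1", dtype)
        self.fc2 = Linear(d_hidden, d_out, rng, f"{name}.fc2", dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.0):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
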