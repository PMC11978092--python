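"""Neural-network building blocks on top of :mod:`pathdrug.nn.tensor`.

Initialization is driven by an explicit ``numpy.random.Generator`` so that
model construction is fully reproducible from a seed.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .tensor import Array, Tensor


def parameter(data: Array) -> Tensor:
    return Tensor(data, requires_grad=True)


class Module:
    """Minimal module base: parameter discovery, train/eval, state dict."""

    def __init__(self) -> None:
        self.training = True

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> dict[str, Array]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, Array]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)[:5]}")
        for name, p in own.items():
            if p.data.shape != np.asarray(state[name]).shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=float).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        bound = 1.0 / math.sqrt(in_dim)
        self.weight = parameter(rng.uniform(-bound, bound, size=(in_dim, out_dim)))
        self.bias = parameter(rng.uniform(-bound, bound, size=(out_dim,)))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.weight = parameter(rng.normal(0.0, 1.0, size=(num_embeddings, dim)))
        self.num_embeddings = num_embeddings

    def forward(self, codes: Array) -> Tensor:
        codes = np.asarray(codes)
        if codes.max(initial=0) >= self.num_embeddings:
            raise IndexError(
                f"token id {int(codes.max())} out of range for vocabulary of "
                f"size {self.num_embeddings}"
            )
        return self.weight.take_rows(codes)


class Conv1dSame(Module):
    """1-D convolution along the sequence with same-length padding.

    Kernels span the full embedding depth: input (B, S, E), weight
    (k, E, C), output (B, S, C) — so attention indexed on the output still
    aligns with token positions.
    """

    def __init__(self, in_dim: int, out_dim: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same-length padding")
        bound = 1.0 / math.sqrt(in_dim * kernel)
        self.weight = parameter(rng.uniform(-bound, bound, size=(kernel, in_dim, out_dim)))
        self.bias = parameter(rng.uniform(-bound, bound, size=(out_dim,)))
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        k = self.kernel
        B, S, E = x.shape
        C = self.weight.shape[2]
        p = k // 2
        xp = np.pad(x.data, ((0, 0), (p, p), (0, 0)))
        cols = np.stack([xp[:, i:i + S, :] for i in range(k)], axis=2)  # (B,S,k,E)
        cols2 = cols.reshape(B, S, k * E)
        wmat = self.weight.data.reshape(k * E, C)
        out = Tensor(cols2 @ wmat + self.bias.data, _prev=(x, self.weight, self.bias))
        weight, bias = self.weight, self.bias

        def backward(g: Array) -> None:
            if bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 1)))
            if weight.requires_grad:
                gw = np.einsum("bsf,bsc->fc", cols2, g)
                weight._accumulate(gw.reshape(k, E, C))
            if x.requires_grad:
                gcols = (g @ wmat.T).reshape(B, S, k, E)
                gxp = np.zeros_like(xp)
                for i in range(k):
                    gxp[:, i:i + S, :] += gcols[:, :, i, :]
                x._accumulate(gxp[:, p:p + S, :])

        out._backward = backward
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc * (var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class BatchNorm1d(Module):
    """Batch normalization over the feature axis of (B, F) inputs."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data[0]
            )
            n = x.shape[0]
            unbiased = var.data[0] * (n / max(n - 1, 1))
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * unbiased
            )
            xhat = xc * (var + self.eps) ** -0.5
        else:
            xhat = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class MultiheadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator) -> None:
        super().__init__()
        if dim % heads != 0:
            raise ValueError(f"embed dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.head_dim = dim // heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.out = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, S, E = x.shape
        h, d = self.heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, S, h, d).swapaxes(1, 2)  # (B,h,S,d)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(d))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).swapaxes(1, 2).reshape(B, S, E)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm transformer encoder layer (self-attention + feed-forward)."""

    def __init__(
        self, dim: int, heads: int, ff_dim: int, dropout: float, rng: np.random.Generator
    ) -> None:
        super().__init__()
        self.attn = MultiheadSelfAttention(dim, heads, rng)
        self.ln1 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)
        self.ln2 = LayerNorm(dim)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.ln1(x + self.drop(self.attn(x)))
        x = self.ln2(x + self.drop(self.ff2(self.drop(self.ff1(x).relu()))))
        return x


class TransformerEncoder(Module):
    def __init__(
        self,
        dim: int,
        heads: int,
        ff_dim: int,
        layers: int,
        dropout: float,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        self.layers = [
            TransformerEncoderLayer(dim, heads, ff_dim, dropout, rng)
            for _ in range(layers)
        ]

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def sinusoidal_positions(seq_len: int, dim: int) -> Array:
    """Fixed sinusoidal positional-encoding matrix (S, E)."""
    pos = np.arange(seq_len)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc
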