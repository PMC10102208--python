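"""Neural-network layers built on the autodiff core.

Layers follow the familiar module pattern: parameters are `Tensor`s with
``requires_grad=True``, a module's ``parameters()`` yields them recursively,
and ``train()`` / ``eval()`` toggle dropout. Initialization draws from an
explicit ``numpy.random.Generator`` so every model build is reproducible.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, concatenate, softmax

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "Dropout",
    "MultiheadSelfAttention",
    "TransformerEncoderLayer",
    "TransformerEncoder",
    "GatedAttentionPool",
]


class Module:
    def __init__(self):
        self.training = True

    def parameters(self):
        seen = set()
        for value in vars(self).values():
            for p in _collect(value, seen):
                yield p

    def named_modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.named_modules()
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        yield from v.named_modules()

    def train(self):
        for m in self.named_modules():
            m.training = True
        return self

    def eval(self):
        for m in self.named_modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = list(self.parameters())
        if len(params) != len(state):
            raise ValueError("state dict does not match model parameter count")
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)])
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.astype(np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(value, seen):
    if isinstance(value, Tensor) and value.requires_grad and id(value) not in seen:
        seen.add(id(value))
        yield value
    elif isinstance(value, Module):
        for v in vars(value).values():
            yield from _collect(v, seen)
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v, seen)


class Linear(Module):
    """Affine map ``x @ W + b`` with Glorot-uniform init."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        bound = math.sqrt(6.0 / (in_dim + out_dim))
        self.weight = Tensor(rng.uniform(-bound, bound, size=(in_dim, out_dim)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered * ((var + self.eps) ** -0.5)
        return normed * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Uses a per-module generator
    seeded at construction so training runs are reproducible."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self._rng = np.random.default_rng(rng.integers(2**31))

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self._rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class MultiheadSelfAttention(Module):
    """Standard scaled dot-product self-attention over a (n_tokens, dim) set."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads != 0:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.out = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        qkv = self.qkv(x)  # (n, 3*dim)
        qkv = qkv.reshape(n, 3, self.n_heads, self.head_dim).transpose(1, 2, 0, 3)
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (heads, n, head_dim)
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / math.sqrt(self.head_dim))
        attn = softmax(scores, axis=-1)
        ctx = attn @ v  # (heads, n, head_dim)
        ctx = ctx.transpose(1, 0, 2).reshape(n, self.dim)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Pre-norm transformer block: LN → MHSA → residual, LN → MLP → residual."""

    def __init__(self, dim: int, n_heads: int, mlp_dim: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = MultiheadSelfAttention(dim, n_heads, rng)
        self.drop1 = Dropout(dropout, rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_dim, rng)
        self.fc2 = Linear(mlp_dim, dim, rng)
        self.drop2 = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.drop1(self.attn(self.norm1(x)))
        h = self.fc2(self.fc1(self.norm2(x)).relu())
        return x + self.drop2(h)


class TransformerEncoder(Module):
    def __init__(self, dim: int, n_heads: int, mlp_dim: int, dropout: float,
                 depth: int, rng: np.random.Generator):
        super().__init__()
        self.layers = [TransformerEncoderLayer(dim, n_heads, mlp_dim, dropout, rng)
                       for _ in range(depth)]
        self.norm = LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return self.norm(x)


class GatedAttentionPool(Module):
    """Gated attention-MIL pooling of a (n, dim) token set to a (dim,) vector.

    Attention logit per token: ``w^T (tanh(V h) * sigmoid(U h))``; weights are
    the softmax over tokens, so they are nonnegative and sum to one. With
    ``gated=False`` the sigmoid gate is dropped (plain tanh attention).
    """

    def __init__(self, dim: int, attn_dim: int, rng: np.random.Generator,
                 gated: bool = True):
        super().__init__()
        self.V = Linear(dim, attn_dim, rng)
        self.U = Linear(dim, attn_dim, rng) if gated else None
        self.w = Linear(attn_dim, 1, rng)
        self.gated = gated

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = self.V(x).tanh()
        if self.gated:
            h = h * self.U(x).sigmoid()
        logits = self.w(h).reshape(x.shape[0])  # (n,)
        weights = softmax(logits, axis=-1)
        pooled = weights @ x  # (dim,)
        return pooled, weights
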