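"""Neural-network building blocks for the 1-D ECG encoder.

A small module system over :mod:`ecgfewshot.nn.autodiff`: linear layers,
strided 1-D convolutions, layer norm and multi-head self-attention, composed
into a lightweight conv + attention encoder that maps a (12, 1000) record to
a 64-dimensional representation.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv1d, softmax

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerBlock",
]


class Module:
    """Base class: parameter discovery, state dicts, parameter counting."""

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                params[full] = value
            elif isinstance(value, Module):
                params.update(value.named_parameters(f"{full}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        params.update(item.named_parameters(f"{full}.{i}."))
        return params

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True) -> None:
        own = self.named_parameters()
        missing = set(own) - set(state)
        if strict and missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for k, v in state.items():
            if k not in own:
                if strict:
                    raise KeyError(f"unexpected parameter {k!r}")
                continue
            if own[k].data.shape != v.shape:
                raise ValueError(
                    f"shape mismatch for {k!r}: {own[k].data.shape} vs {v.shape}"
                )
            own[k].data = np.asarray(v, dtype=own[k].data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


# models are trained in float32; the autodiff engine preserves dtype
DTYPE = np.float32


def _kaiming(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Tensor(_kaiming(rng, d_in, (d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator):
        self.stride = stride
        self.W = Tensor(_kaiming(rng, c_in * kernel, (c_out, c_in, kernel)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.W, self.b, stride=self.stride)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones(dim, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention over the time axis."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads != 0:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.dim = dim
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.out = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        H, Dh = self.n_heads, self.d_head
        qkv = self.qkv(x).reshape(B, T, 3, H, Dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (B, H, T, Dh)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(Dh))
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.out(ctx)


class TransformerBlock(Module):
    """Pre-norm attention block with a small ReLU feed-forward sublayer."""

    def __init__(self, dim: int, n_heads: int, ffn_dim: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.ffn1 = Linear(dim, ffn_dim, rng)
        self.ffn2 = Linear(ffn_dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.ffn2(self.ffn1(self.ln2(x)).relu())
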