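"""Encoder, projection head and classifier architectures.

The encoder is a lightweight 1-D CNN front-end (strided convolutions with
ReLU) followed by self-attention blocks over the downsampled time axis and
mean pooling, producing a 64-dimensional representation h.  The projection
head is the standard two-layer ReLU MLP (64 -> 128 -> 64) used only during
contrastive pretraining; the classifier attaches a linear 64 -> 5 head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .layers import Conv1d, Linear, Module, TransformerBlock

__all__ = [
    "EncoderSpec",
    "ProjectionSpec",
    "Encoder",
    "ProjectionHead",
    "Classifier",
    "DEFAULT_ENCODER_SPEC",
    "TINY_ENCODER_SPEC",
]


@dataclass(frozen=True)
class EncoderSpec:
    """Architecture of the conv + attention encoder.

    ``conv_blocks`` is a list of (channels, kernel, stride); the last block's
    channel count must equal ``embed_dim``, which must equal ``rep_dim`` (64).
    """

    conv_blocks: tuple[tuple[int, int, int], ...] = ((16, 7, 2), (32, 5, 2), (64, 3, 2))
    attn_layers: int = 2
    attn_heads: int = 4
    embed_dim: int = 64
    ffn_dim: int = 128
    rep_dim: int = 64

    def __post_init__(self) -> None:
        if self.rep_dim != 64:
            raise ValueError("rep_dim is fixed at 64")
        if self.conv_blocks[-1][0] != self.embed_dim:
            raise ValueError("last conv channel count must equal embed_dim")
        if self.embed_dim != self.rep_dim:
            raise ValueError("embed_dim must equal rep_dim")


DEFAULT_ENCODER_SPEC = EncoderSpec()

# Smaller preset for CPU-scale end-to-end runs: one attention block, heavier
# initial stride, ~30k parameters (still well under the 1e6 lightweight cap).
TINY_ENCODER_SPEC = EncoderSpec(
    conv_blocks=((8, 7, 4), (16, 5, 2), (64, 3, 2)),
    attn_layers=1,
    attn_heads=2,
    ffn_dim=64,
)


@dataclass(frozen=True)
class ProjectionSpec:
    """Contrastive projection head: two affine layers 64 -> 128 -> 64, ReLU."""

    dims: tuple[int, int, int] = (64, 128, 64)

    def __post_init__(self) -> None:
        if len(self.dims) != 3:
            raise ValueError("projection head has exactly two affine layers")


class Encoder(Module):
    """Maps (B, 12, T) signals to (B, 64) representations.

    The last convolutional feature map of the most recent forward pass is
    kept on ``self.last_conv`` (a graph tensor), so its gradient is available
    after ``backward`` — used by 1-D Grad-CAM.
    """

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator, in_channels: int = 12):
        self.spec = spec
        convs = []
        c_prev = in_channels
        for channels, kernel, stride in spec.conv_blocks:
            convs.append(Conv1d(c_prev, channels, kernel, stride, rng))
            c_prev = channels
        self.convs = convs
        self.blocks = [
            TransformerBlock(spec.embed_dim, spec.attn_heads, spec.ffn_dim, rng)
            for _ in range(spec.attn_layers)
        ]
        self.last_conv: Tensor | None = None
        if self.n_parameters() >= 1_000_000:
            raise ValueError("encoder exceeds the lightweight 1e6-parameter budget")

    def forward(self, x: Tensor) -> Tensor:
        for conv in self.convs:
            x = conv(x).relu()
        self.last_conv = x  # (B, C=embed_dim, T')
        x = x.swapaxes(1, 2)  # tokens over time: (B, T', D)
        for block in self.blocks:
            x = block(x)
        return x.mean(axis=1)  # (B, rep_dim)


class ProjectionHead(Module):
    def __init__(self, spec: ProjectionSpec, rng: np.random.Generator):
        d_in, d_hidden, d_out = spec.dims
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_out, rng)

    def forward(self, h: Tensor) -> Tensor:
        return self.fc2(self.fc1(h).relu())


class Classifier(Module):
    """Encoder plus linear classification head over the five rhythm classes."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator, n_classes: int = 5):
        self.encoder = Encoder(spec, rng)
        self.head = Linear(spec.rep_dim, n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.encoder(x))
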