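"""Efficient channel attention (ECA) and the global attention mechanism (GAM).

Both operators are shape-preserving gates: they compute a sigmoid attention
map from the input feature tensor and multiply it elementwise onto the input.

ECA pools each channel to a scalar (global average pooling), runs a single
weight-shared, bias-free 1-D convolution of kernel size ``k`` across the
channel axis and gates with a sigmoid; its trainable cost is exactly ``k``
parameters.  The adaptive kernel rule maps channel count ``C`` to the odd
integer nearest ``log2(C)/gamma + b/gamma``; in practice the detector uses a
fixed ``k = 3`` (see :class:`EcaConfig`).

GAM applies channel attention (a spatially shared two-layer perceptron over
the channel axis, reduction rate ``r``) followed by spatial attention (two
7x7 convolutions with batch normalization and no pooling), each gated by a
sigmoid.  For reduction rate 4 a GAM on ``C`` channels carries exactly
``25*C**2 + 5*C`` trainable parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .nn import (BatchNorm2d, Conv2d, Linear, Module, Parameter, Tensor,
                 conv1d_channels)

__all__ = ["EcaConfig", "GamConfig", "eca_kernel_size", "EcaGate",
           "GamChannelAttention", "GamSpatialAttention", "Gam",
           "gam_param_count"]


def eca_kernel_size(c: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Adaptive ECA kernel size: odd integer nearest ``log2(c)/gamma + b/gamma``.

    Half-integer ties (equidistant odd neighbours) round downward, and the
    result is floored at 1.
    """
    if c < 1:
        raise ValueError(f"channel count must be positive, got {c}")
    t = math.log2(c) / gamma + b / gamma
    lo = max(1, 2 * math.floor((t - 1) / 2) + 1)  # largest odd <= t, >= 1
    hi = lo + 2
    # tie -> smaller odd number
    k = lo if (t - lo) <= (hi - t) else hi
    return max(1, k)


@dataclass
class EcaConfig:
    """ECA hyper-parameters; ``fixed3`` pins k=3 regardless of width."""

    gamma: float = 2.0
    b: float = 1.0
    kernel_mode: str = "fixed3"  # "fixed3" | "adaptive"

    def kernel_for(self, channels: int) -> int:
        if self.kernel_mode == "fixed3":
            return 3
        if self.kernel_mode == "adaptive":
            return eca_kernel_size(channels, self.gamma, self.b)
        raise ValueError(f"unknown kernel_mode {self.kernel_mode!r}")


@dataclass
class GamConfig:
    channels: int = 256
    reduction: int = 4
    spatial_kernel: int = 7

    def __post_init__(self):
        if self.channels % self.reduction:
            raise ValueError(
                f"channels ({self.channels}) must be divisible by the "
                f"reduction rate ({self.reduction})")


class EcaGate(Module):
    """Channel gate: GAP -> shared bias-free 1-D conv (k taps) -> sigmoid."""

    def __init__(self, channels: int, cfg: EcaConfig | None = None):
        super().__init__()
        cfg = cfg or EcaConfig()
        self.k = cfg.kernel_for(channels)
        if self.k % 2 == 0:
            raise ValueError(f"ECA kernel size must be odd, got {self.k}")
        self.weight = Parameter(np.zeros(self.k))
        self.weight.data[self.k // 2] = 1.0  # identity-ish start

    def forward(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3))                # (B, C)
        gate = conv1d_channels(pooled, self.weight).sigmoid()
        b, c = gate.shape
        return x * gate.reshape(b, c, 1, 1)


class GamChannelAttention(Module):
    """Per-position two-layer MLP over channels (weights shared over H, W)."""

    def __init__(self, cfg: GamConfig, rng: np.random.Generator | None = None):
        super().__init__()
        c, r = cfg.channels, cfg.reduction
        self.fc1 = Linear(c, c // r, bias=True, rng=rng)
        self.fc2 = Linear(c // r, c, bias=True, rng=rng)

    def attention_map(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        flat = x.transpose(0, 2, 3, 1).reshape(b * h * w, c)
        hidden = self.fc1(flat).relu()
        logits = self.fc2(hidden).reshape(b, h, w, c).transpose(0, 3, 1, 2)
        return logits.sigmoid()

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        mc = self.attention_map(x)
        return mc, mc * x


class GamSpatialAttention(Module):
    """Two 7x7 convolutions (C -> C/r -> C) with batch norm; no pooling."""

    def __init__(self, cfg: GamConfig, rng: np.random.Generator | None = None):
        super().__init__()
        c, r, k = cfg.channels, cfg.reduction, cfg.spatial_kernel
        self.conv1 = Conv2d(c, c // r, k, bias=True, rng=rng)
        self.bn1 = BatchNorm2d(c // r)
        self.conv2 = Conv2d(c // r, c, k, bias=True, rng=rng)
        self.bn2 = BatchNorm2d(c)

    def attention_map(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y))
        return y.sigmoid()

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        ms = self.attention_map(x)
        return ms, ms * x


class Gam(Module):
    """Sequential channel then spatial attention."""

    def __init__(self, channels: int, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = GamConfig(channels=channels, reduction=reduction)
        self.channel = GamChannelAttention(cfg, rng=rng)
        self.spatial = GamSpatialAttention(cfg, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        _, f2 = self.channel(x)
        _, f3 = self.spatial(f2)
        return f3


def gam_param_count(channels: int, reduction: int = 4) -> int:
    """Closed-form trainable-parameter count of a GAM.

    For reduction 4 this is ``25*C**2 + 5*C``: the channel MLP contributes
    ``C**2/2 + 5C/4`` (two biased linear layers), the spatial path
    ``24.5*C**2 + 15C/4`` (two biased 7x7 convolutions plus two affine batch
    norms).
    """
    if channels % reduction:
        raise ValueError("channels must be divisible by reduction")
    c, r = channels, reduction
    hidden = c // r
    mlp = (c * hidden + hidden) + (hidden * c + c)
    spatial = (49 * c * hidden + hidden) + 2 * hidden \
        + (49 * hidden * c + c) + 2 * c
    return mlp + spatial
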