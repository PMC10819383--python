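"""Local-feature extractors: the stem convolution and MobileNetV2-style
inverted residual blocks.

Convolutions are bias-free and every convolution is followed by a
parameter-free batch normalization; SiLU activation follows the first two
convolutions of an inverted residual (never the projection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor
from .nn.layers import BatchNorm2d, Conv2d, Module

__all__ = ["InvertedResidualConfig", "InvertedResidual", "Stem"]


@dataclass(frozen=True)
class InvertedResidualConfig:
    in_channels: int
    out_channels: int
    expansion_ratio: float
    stride: int = 1

    @property
    def hidden_channels(self) -> int:
        return round(self.expansion_ratio * self.in_channels)

    @property
    def has_shortcut(self) -> bool:
        return self.stride == 1 and self.in_channels == self.out_channels


def _act(x: Tensor, kind: str) -> Tensor:
    if kind == "silu":
        return x.silu()
    if kind == "relu6":
        return Tensor(np.minimum(x.relu().data, 6.0)) if not x.requires_grad else \
            -((-x.relu()) + 6.0).relu() + 6.0
    raise ValueError(f"unknown activation {kind!r}")


class InvertedResidual(Module):
    """1x1 expand -> 3x3 depthwise -> 1x1 project, with optional shortcut.

    The expansion convolution is omitted when the ratio is 1 (it would be a
    square map that the depthwise stage cannot use).
    """

    def __init__(self, cfg: InvertedResidualConfig, activation: str = "silu",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.activation = activation
        h = cfg.hidden_channels
        if cfg.expansion_ratio != 1:
            self.expand = Conv2d(cfg.in_channels, h, 1, rng=rng)
            self.expand_norm = BatchNorm2d(h)
        else:
            self.expand = None
            self.expand_norm = None
        self.depthwise = Conv2d(h, h, 3, stride=cfg.stride, padding=1, groups=h,
                                rng=rng)
        self.depthwise_norm = BatchNorm2d(h)
        self.project = Conv2d(h, cfg.out_channels, 1, rng=rng)
        self.project_norm = BatchNorm2d(cfg.out_channels)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}")
        y = x
        if self.expand is not None:
            y = _act(self.expand_norm(self.expand(y)), self.activation)
        y = _act(self.depthwise_norm(self.depthwise(y)), self.activation)
        y = self.project_norm(self.project(y))
        if self.cfg.has_shortcut:
            y = y + x
        return y


class Stem(Module):
    """3x3 stride-2 convolution from RGB to the first feature width."""

    def __init__(self, out_channels: int, activation: str = "silu",
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(3, out_channels, 3, stride=2, padding=1, rng=rng)
        self.norm = BatchNorm2d(out_channels)
        self.activation = activation

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != 3:
            raise ValueError(f"stem expects 3-channel input, got {x.shape[1]}")
        return _act(self.norm(self.conv(x)), self.activation)
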