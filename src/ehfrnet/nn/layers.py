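"""Neural-network building blocks over the autograd core.

Conventions (calibrated to the published model sizes):

* convolutions and the attention projections are bias-free;
* normalization layers are parameter-free — any affine rescaling is absorbed
  by the adjacent linear maps;
* the default activation is SiLU.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

__all__ = [
    "Parameter", "Module", "Sequential", "Conv2d", "Linear", "BatchNorm2d",
    "channel_layer_norm", "SiLU", "ReLU", "Identity", "GlobalAvgPool2d",
    "trunc_normal", "kaiming_normal",
]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) clipped to ±2 std — transformer-style linear init."""
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std)


def kaiming_normal(rng: np.random.Generator, shape) -> np.ndarray:
    """Fan-out He init for convolution weights (Cout, Cin/g, kh, kw)."""
    fan_out = shape[0] * shape[2] * shape[3]
    return rng.normal(0.0, np.sqrt(2.0 / fan_out), size=shape)


class Module:
    """Minimal module tree: attribute discovery of parameters and children."""

    def __init__(self):
        self.training = True

    # attribute walking -------------------------------------------------------
    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, child in self.children():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_modules(sub)

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield (f"{prefix}.{name}" if prefix else name), value
        for name, child in self.children():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_parameters(sub)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # train/eval --------------------------------------------------------------
    def train(self):
        for _, m in self.named_modules():
            m.training = True
        return self

    def eval(self):
        for _, m in self.named_modules():
            m.training = False
        return self

    # state -------------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self.named_modules():
            if isinstance(m, BatchNorm2d):
                key = f"{name}." if name else ""
                state[f"{key}running_mean"] = m.running_mean.copy()
                state[f"{key}running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=p.data.dtype).reshape(p.shape)
        for name, m in self.named_modules():
            if isinstance(m, BatchNorm2d):
                key = f"{name}." if name else ""
                m.running_mean = np.asarray(state[f"{key}running_mean"]).copy()
                m.running_var = np.asarray(state[f"{key}running_var"]).copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self.layers)

    def __len__(self):
        return len(self.layers)


class Conv2d(Module):
    """Bias-free grouped 2-D convolution."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        rng = rng or np.random.default_rng(0)
        shape = (out_channels, in_channels // groups, kernel_size, kernel_size)
        self.weight = Parameter(kaiming_normal(rng, shape))
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}")
        return conv2d(x, self.weight, self.stride, self.padding, self.groups)


class Linear(Module):
    """Affine map on the last axis; bias optional."""

    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(trunc_normal(rng, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None
        self.in_features = in_features
        self.out_features = out_features

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_features:
            raise ValueError(
                f"expected {self.in_features} input features, got {x.shape[-1]}")
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Parameter-free batch normalization over (B, H, W) per channel.

    Keeps running statistics for evaluation mode; carries no affine weights
    (the calibrated counting convention — scale/shift live in the neighbouring
    convolutions).
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(-1))
            return (x - mu) / (var + self.eps).sqrt()
        mu = self.running_mean.reshape(1, -1, 1, 1)
        var = self.running_var.reshape(1, -1, 1, 1)
        return (x - Tensor(mu)) * Tensor(1.0 / np.sqrt(var + self.eps))


def channel_layer_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Parameter-free layer normalization over the channel axis (axis 1)."""
    mu = x.mean(axis=1, keepdims=True)
    centered = x - mu
    var = (centered ** 2.0).mean(axis=1, keepdims=True)
    return centered / (var + eps).sqrt()


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class GlobalAvgPool2d(Module):
    """(B, C, H, W) -> (B, C)."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))
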