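"""Assembly of the full hybrid network from its published layout.

Five hybrid groups (HBlocks) follow a stride-2 stem.  Each group stacks
inverted residual blocks (local features) and location-preserving ViT blocks
(global features), fused by an element-wise skip sum.  Channel widths are
``round(base * alpha)`` for bases 32/64/96/160/320; spatial resolution halves
at the stem and at the first block of groups 2-5 (256 -> 128 -> 64 -> 32 ->
16 -> 8), and a global-average-pool + affine head produces the logits.

Ablation variants are built from the same configuration: ``cnn_only`` drops
the attention stacks, ``vit_only`` replaces each group's convolution stack
with a single strided downsampling convolution, and ``mha`` swaps every
LP-ViT block for a quadratic multi-head attention block.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .attention import LPViTBlock, MHABlock
from .backbone import InvertedResidual, InvertedResidualConfig, Stem
from .nn.autograd import Tensor
from .nn.layers import BatchNorm2d, Conv2d, GlobalAvgPool2d, Linear, Module

__all__ = [
    "TABLE_LAYOUT", "NetworkConfig", "HBlock", "EHFRNet", "build_network",
    "save_checkpoint", "load_checkpoint",
]

# (base output channels, [(expansion ratio, stride), ...], LP-ViT block count)
TABLE_LAYOUT: tuple[tuple[int, list[tuple[float, int]], int], ...] = (
    (32,  [(1, 1), (1, 1)],          1),
    (64,  [(1, 2), (1, 1), (3, 1)],  2),
    (96,  [(3, 2), (3, 1), (3, 1)],  3),
    (160, [(6, 2), (2.5, 1), (2.5, 1)], 2),
    (320, [(6, 2)],                  1),
)

VARIANTS = ("full", "cnn_only", "vit_only", "mha")


@dataclass
class NetworkConfig:
    """Everything that determines the architecture (and hence its size)."""

    alpha: float = 1.0
    num_classes: int = 101
    patch_size: tuple[int, int] = (2, 2)
    variant: str = "full"
    mha_heads: int = 4
    activation: str = "silu"
    ffn_activation: str | None = "silu"
    patch_weight_axis: str = "channel"
    use_norm: bool = True
    use_residual: bool = True

    def __post_init__(self):
        if not 0.5 <= self.alpha <= 2.0:
            raise ValueError(f"alpha must lie in [0.5, 2.0], got {self.alpha}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be at least 2")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        self.patch_size = tuple(self.patch_size)

    def channels(self) -> list[int]:
        return [round(base * self.alpha) for base, _, _ in TABLE_LAYOUT]

    def stem_channels(self) -> int:
        return round(32 * self.alpha)


class Downsample(Module):
    """Strided 3x3 convolution used by the attention-only variant."""

    def __init__(self, cin: int, cout: int, rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, 3, stride=2, padding=1, rng=rng)
        self.norm = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x)).silu()


class HBlock(Module):
    """A convolution stack followed by an attention stack with a skip sum."""

    def __init__(self, conv_blocks: list[Module], vit_blocks: list[Module],
                 skip_fusion: bool = True):
        super().__init__()
        self.conv_blocks = list(conv_blocks)
        self.vit_blocks = list(vit_blocks)
        self.skip_fusion = skip_fusion

    def forward(self, x: Tensor) -> Tensor:
        for block in self.conv_blocks:
            x = block(x)
        if not self.vit_blocks:
            return x
        y = x
        for block in self.vit_blocks:
            y = block(y)
        return y + x if self.skip_fusion else y


class EHFRNet(Module):
    """The assembled classifier."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.stem = Stem(cfg.stem_channels(), cfg.activation, rng=rng)
        groups: list[HBlock] = []
        cin = cfg.stem_channels()
        for gi, ((base, ir_specs, n_vit), cout) in enumerate(
                zip(TABLE_LAYOUT, cfg.channels())):
            convs: list[Module] = []
            if cfg.variant == "vit_only":
                if gi > 0:
                    convs.append(Downsample(cin, cout, rng=rng))
                block_in = cout
            else:
                block_in = cin
                for ratio, stride in ir_specs:
                    ircfg = InvertedResidualConfig(block_in, cout, ratio, stride)
                    convs.append(InvertedResidual(ircfg, cfg.activation, rng=rng))
                    block_in = cout
            vits: list[Module] = []
            if cfg.variant != "cnn_only":
                for _ in range(n_vit):
                    if cfg.variant == "mha":
                        vits.append(MHABlock(cout, cfg.mha_heads, cfg.patch_size,
                                             rng=rng))
                    else:
                        vits.append(LPViTBlock(
                            cout, cfg.patch_size, cfg.ffn_activation,
                            cfg.patch_weight_axis, cfg.use_norm,
                            cfg.use_residual, rng=rng))
            groups.append(HBlock(convs, vits))
            cin = cout
        self.groups = groups
        self.pool = GlobalAvgPool2d()
        self.head = Linear(cfg.channels()[-1], cfg.num_classes, bias=True, rng=rng)

    def layer_names(self) -> list[str]:
        return ["stem"] + [f"group{i + 1}" for i in range(len(self.groups))]

    def features(self, x: Tensor, capture: dict | None = None) -> Tensor:
        y = self.stem(x)
        if capture is not None:
            capture["stem"] = y
        for i, group in enumerate(self.groups):
            y = group(y)
            if capture is not None:
                capture[f"group{i + 1}"] = y
        return y

    def forward(self, x: Tensor, capture: dict | None = None) -> Tensor:
        return self.head(self.pool(self.features(x, capture)))


def build_network(cfg: NetworkConfig | None = None, seed: int = 0,
                  **kwargs) -> EHFRNet:
    """Construct the network; ``kwargs`` override config fields."""
    if cfg is None:
        cfg = NetworkConfig(**kwargs)
    elif kwargs:
        cfg = NetworkConfig(**{**asdict(cfg), **kwargs})
    return EHFRNet(cfg, seed=seed)


def build_variant(name: str, alpha: float = 1.0, num_classes: int = 101,
                  seed: int = 0, **kwargs) -> EHFRNet:
    return build_network(NetworkConfig(alpha=alpha, num_classes=num_classes,
                                       variant=name, **kwargs), seed=seed)


def save_checkpoint(model: EHFRNet, path, iteration: int = 0,
                    extra: dict | None = None) -> None:
    """Bundle weights, the generating config and an iteration counter."""
    meta = {"config": asdict(model.cfg), "iteration": iteration,
            "extra": extra or {}}
    buf = io.BytesIO()
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(buf, __meta__=np.frombuffer(
        yaml.safe_dump(meta).encode(), dtype=np.uint8), **arrays)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_checkpoint(path) -> tuple[EHFRNet, dict]:
    with np.load(path) as data:
        meta = yaml.safe_load(bytes(data["__meta__"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    cfg_dict = meta["config"]
    cfg = NetworkConfig(**cfg_dict)
    model = EHFRNet(cfg)
    model.load_state_dict(state)
    return model, meta
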