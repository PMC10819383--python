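"""Exact parameter counting and multiply-accumulate (MAC) profiling.

Counting convention, also printed in every report header:

* parameters — every trainable array in the model, enumerated exactly;
* MACs — multiplications of convolutions, affine maps and attention
  contractions (projections, score/context reductions, token-pair products
  for the quadratic reference block); normalization, softmax, activations,
  pooling and plain element-wise products are excluded.

Published "#FLOPs" columns for this model family are MAC counts; they are
labelled MACs here and no exact figure is asserted against them (the source
tables disagree with each other at the 2% level for identical
configurations).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass

from .attention import LPViTBlock, MHABlock
from .backbone import InvertedResidual, Stem
from .network import Downsample, EHFRNet

__all__ = ["ProfileReport", "count_parameters", "count_macs", "report"]

CONVENTION = ("params: all trainable arrays; MACs: conv/affine/attention "
              "contractions at the stated input, norm/softmax/activation/"
              "elementwise excluded")


@dataclass
class ProfileRow:
    name: str
    params: int
    macs: int


@dataclass
class ProfileReport:
    rows: list[ProfileRow]
    input_shape: tuple[int, ...] | None
    convention: str = CONVENTION

    @property
    def total_params(self) -> int:
        return sum(r.params for r in self.rows)

    @property
    def total_macs(self) -> int:
        return sum(r.macs for r in self.rows)

    @property
    def params_millions(self) -> float:
        return self.total_params / 1e6

    @property
    def macs_millions(self) -> float:
        return self.total_macs / 1e6

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["module", "params", "macs"])
        for row in self.rows:
            writer.writerow([row.name, row.params, row.macs])
        writer.writerow(["total", self.total_params, self.total_macs])
        return buf.getvalue()

    def table(self) -> str:
        width = max(len(r.name) for r in self.rows + [ProfileRow("total", 0, 0)])
        lines = [f"# {self.convention}"]
        if self.input_shape is not None:
            lines.append(f"# input shape: {self.input_shape}")
        lines.append(f"{'module'.ljust(width)}  {'params':>12}  {'MACs':>14}")
        for row in self.rows:
            lines.append(f"{row.name.ljust(width)}  {row.params:>12}  {row.macs:>14}")
        lines.append(f"{'total'.ljust(width)}  {self.total_params:>12}  "
                     f"{self.total_macs:>14}")
        lines.append(f"total: {self.params_millions:.2f} M params, "
                     f"{self.macs_millions:.2f} M MACs")
        return "\n".join(lines)


def _conv_macs(conv, hin: int, win: int) -> tuple[int, int, int]:
    ho = (hin + 2 * conv.padding - conv.kernel_size) // conv.stride + 1
    wo = (win + 2 * conv.padding - conv.kernel_size) // conv.stride + 1
    macs = (conv.out_channels * (conv.in_channels // conv.groups)
            * conv.kernel_size ** 2 * ho * wo)
    return macs, ho, wo


def _block_macs(block, h: int, w: int) -> tuple[int, int, int]:
    """MACs for one leaf block at spatial size (h, w); returns output size."""
    if isinstance(block, (Stem, Downsample)):
        return _conv_macs(block.conv, h, w)
    if isinstance(block, InvertedResidual):
        total = 0
        if block.expand is not None:
            m, _, _ = _conv_macs(block.expand, h, w)
            total += m
        m, ho, wo = _conv_macs(block.depthwise, h, w)
        total += m
        m, _, _ = _conv_macs(block.project, ho, wo)
        return total + m, ho, wo
    if isinstance(block, LPViTBlock):
        C = block.channels
        T = h * w
        proj = 5 * C * C * T + 2 * C * T          # W_K/W_V x2 branches, W_O, W_I x2
        if block.intra_patch.weight_axis == "patch":
            P = block.intra_patch.patch_len
            proj = 3 * C * C * T + C * T + 2 * P * P * T + P * T
        ffn = 4 * C * C * T
        context = 2 * C * T                       # two weighted-sum reductions
        return proj + ffn + context, h, w
    if isinstance(block, MHABlock):
        C = block.channels
        ph, pw = block.patch_shape
        P = ph * pw
        N = (h * w) // P
        T = h * w
        qkv = 3 * C * C * T
        scores = N * C * T                        # Q K^T over all positions
        weighted = N * C * T                      # attention-weighted values
        out = C * C * T
        ffn = 4 * C * C * T
        return qkv + scores + weighted + out + ffn, h, w
    raise TypeError(f"no MAC rule for {type(block).__name__}")


def _walk(model: EHFRNet, input_shape) -> list[ProfileRow]:
    rows: list[ProfileRow] = []
    h = w = None
    if input_shape is not None:
        h, w = input_shape[-2], input_shape[-1]

    def add(name, module):
        nonlocal h, w
        macs = 0
        if h is not None:
            macs, h, w = _block_macs(module, h, w)
        rows.append(ProfileRow(name, module.num_parameters(), macs))

    add("stem", model.stem)
    for gi, group in enumerate(model.groups, start=1):
        for bi, block in enumerate(group.conv_blocks):
            add(f"group{gi}.conv.{bi}", block)
        for bi, block in enumerate(group.vit_blocks):
            add(f"group{gi}.vit.{bi}", block)
    head_macs = 0
    if input_shape is not None:
        head_macs = model.head.in_features * model.head.out_features
    rows.append(ProfileRow("head", model.head.num_parameters(), head_macs))
    return rows


def count_parameters(model: EHFRNet) -> ProfileReport:
    """Exact per-module trainable-parameter report (no MACs)."""
    return ProfileReport(_walk(model, None), None)


def count_macs(model: EHFRNet, input_shape=(1, 3, 256, 256)) -> ProfileReport:
    """Parameter and MAC report at the given input shape."""
    return ProfileReport(_walk(model, tuple(input_shape)), tuple(input_shape))


def report(model: EHFRNet, input_shape=(1, 3, 256, 256)) -> ProfileReport:
    return count_macs(model, input_shape)
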