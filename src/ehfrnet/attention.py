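"""Separable attention branches and the location-preserving ViT block.

The block unfolds a feature map into a (B, C, P, N) patch sequence and runs
two linear-complexity attention branches in parallel:

* the **inter-patch** branch treats the N patches as tokens (for each
  within-patch position p) — global context across the image;
* the **intra-patch** (patch attention) branch transposes P and N and treats
  the P pixels inside a patch as tokens — local context within a patch.

Each branch is *separable* self-attention: a context projection scores every
token, a softmax over the token axis turns the scores into weights, and the
weighted sum of key-projected tokens forms a single context vector that
gates the ReLU-rectified value projection.  Cost is linear in the number of
tokens — no token-pair score matrix is ever formed.

Branch outputs are fused by addition and passed through one shared output
projection (the two printed output maps are each other's transpose, i.e. a
single weight), then a two-layer position-wise FFN, and the sequence is
folded back to an image.  Residual connections and parameter-free channel
layer-norms wrap the attention stage and the FFN.
"""

from __future__ import annotations

import numpy as np

from .nn.autograd import Tensor, softmax
from .nn.layers import Module, Parameter, trunc_normal, channel_layer_norm
from .patch_geometry import PatchSequence, fold, patch_transpose, unfold

__all__ = [
    "SeparableSelfAttention", "PatchAttention", "FeedForward", "LPViTBlock",
    "MHABlock",
]


def _channel_linear(x: Tensor, weight: Parameter) -> Tensor:
    """Apply a (Cin, Cout) map along axis 1 of a (B, C, T1, T2) tensor."""
    B, C, a, b = x.shape
    out = x.transpose(0, 2, 3, 1).reshape(B * a * b, C) @ weight
    return out.reshape(B, a, b, weight.shape[1]).transpose(0, 3, 1, 2)


def _attend(x: Tensor, w_i: Parameter, w_k: Parameter, w_v: Parameter,
            token_axis: int) -> Tensor:
    """Separable attention on a (B, C, T1, T2) tensor.

    ``token_axis`` is 2 or 3; the other trailing axis is carried as batch.
    Feature projections act on the channel axis.
    """
    scores = softmax(_channel_linear(x, w_i), axis=token_axis)     # (B,1,T1,T2)
    context = (scores * _channel_linear(x, w_k)).sum(axis=token_axis,
                                                     keepdims=True)
    return context * _channel_linear(x, w_v).relu()


class SeparableSelfAttention(Module):
    """Inter-patch separable self-attention on a (B, C, P, N) sequence.

    Tokens run along the patch-index axis N; weights act on the channel axis.
    ``own_output=False`` omits the output projection so a block can share one
    across branches.
    """

    def __init__(self, channels: int, own_output: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.context_projection = Parameter(trunc_normal(rng, (channels, 1)))
        self.key_map = Parameter(trunc_normal(rng, (channels, channels)))
        self.value_map = Parameter(trunc_normal(rng, (channels, channels)))
        self.output_map = (Parameter(trunc_normal(rng, (channels, channels)))
                           if own_output else None)

    def forward(self, X: PatchSequence) -> PatchSequence:
        x = X.data if isinstance(X.data, Tensor) else Tensor(np.asarray(X.data))
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        out = _attend(x, self.context_projection, self.key_map, self.value_map,
                      token_axis=3)
        if self.output_map is not None:
            out = _channel_linear(out, self.output_map)
        return PatchSequence(out, X.patch_shape, X.origin_shape, X.transposed)


class PatchAttention(Module):
    """Intra-patch branch: transpose, attend over P, transpose back.

    ``weight_axis='channel'`` (default) puts the projection weights on the
    channel axis, the only reading compatible with the published model sizes;
    ``'patch'`` keeps the printed P×P weight shapes for comparison.
    """

    def __init__(self, channels: int, patch_len: int = 4,
                 weight_axis: str = "channel", own_output: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if weight_axis not in ("channel", "patch"):
            raise ValueError(f"unknown weight_axis {weight_axis!r}")
        self.channels = channels
        self.patch_len = patch_len
        self.weight_axis = weight_axis
        dim = channels if weight_axis == "channel" else patch_len
        self.context_projection = Parameter(trunc_normal(rng, (dim, 1)))
        self.key_map = Parameter(trunc_normal(rng, (dim, dim)))
        self.value_map = Parameter(trunc_normal(rng, (dim, dim)))
        self.output_map = (Parameter(trunc_normal(rng, (dim, dim)))
                           if own_output else None)

    def forward(self, X: PatchSequence) -> PatchSequence:
        Xt = patch_transpose(X)                     # (B, C, N, P)
        x = Xt.data
        if self.weight_axis == "channel":
            out = _attend(x, self.context_projection, self.key_map,
                          self.value_map, token_axis=3)
            if self.output_map is not None:
                out = _channel_linear(out, self.output_map)
        else:
            # literal printed shapes: features along P, tokens along N,
            # (B, C) carried as batch
            scores = softmax(x @ self.context_projection, axis=2)
            context = (scores * (x @ self.key_map)).sum(axis=2, keepdims=True)
            out = context * (x @ self.value_map).relu()
            if self.output_map is not None:
                out = out @ self.output_map
        back = PatchSequence(out, Xt.patch_shape, Xt.origin_shape, Xt.transposed)
        return patch_transpose(back)


class FeedForward(Module):
    """Position-wise FFN on the channel axis: C -> 2C -> C.

    The expansion carries a bias; the projection is bias-free (counting
    convention).  ``activation=None`` gives the literal affine composition.
    """

    def __init__(self, channels: int, activation: str | None = "silu",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.activation = activation
        self.expand_map = Parameter(trunc_normal(rng, (channels, 2 * channels)))
        self.expand_bias = Parameter(np.zeros(2 * channels))
        self.project_map = Parameter(trunc_normal(rng, (2 * channels, channels)))

    def forward(self, X: PatchSequence) -> PatchSequence:
        x = X.data if isinstance(X.data, Tensor) else Tensor(np.asarray(X.data))
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        B, C, a, b = x.shape
        h = x.transpose(0, 2, 3, 1).reshape(B * a * b, C) @ self.expand_map
        h = h + self.expand_bias
        if self.activation == "silu":
            h = h.silu()
        elif self.activation == "relu":
            h = h.relu()
        elif self.activation is not None:
            raise ValueError(f"unknown activation {self.activation!r}")
        out = (h @ self.project_map).reshape(B, a, b, C).transpose(0, 3, 1, 2)
        return PatchSequence(out, X.patch_shape, X.origin_shape, X.transposed)


class LPViTBlock(Module):
    """unfold -> (inter-patch ∥ intra-patch) attention -> FFN -> fold.

    Output shape equals input shape; with all weights at zero and residuals
    on, the block is the identity.
    """

    def __init__(self, channels: int, patch_shape: tuple[int, int] = (2, 2),
                 ffn_activation: str | None = "silu",
                 patch_weight_axis: str = "channel",
                 use_norm: bool = True, use_residual: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.patch_shape = tuple(patch_shape)
        self.use_norm = use_norm
        self.use_residual = use_residual
        self.inter_patch = SeparableSelfAttention(channels, own_output=False, rng=rng)
        self.intra_patch = PatchAttention(channels, patch_shape[0] * patch_shape[1],
                                          patch_weight_axis, own_output=False, rng=rng)
        self.output_map = Parameter(trunc_normal(rng, (channels, channels)))
        self.ffn = FeedForward(channels, ffn_activation, rng=rng)

    def _norm(self, X: PatchSequence) -> PatchSequence:
        if not self.use_norm:
            return X
        return PatchSequence(channel_layer_norm(X.data), X.patch_shape,
                             X.origin_shape, X.transposed)

    def forward(self, x: Tensor) -> Tensor:
        X = unfold(x, self.patch_shape)
        Xn = self._norm(X)
        y1 = self.inter_patch(Xn).data
        y2 = self.intra_patch(Xn).data
        fused = _channel_linear(y1 + y2, self.output_map)
        if self.use_residual:
            fused = X.data + fused
        A = PatchSequence(fused, X.patch_shape, X.origin_shape)
        z = self.ffn(self._norm(A)).data
        if self.use_residual:
            z = A.data + z
        return fold(PatchSequence(z, X.patch_shape, X.origin_shape))


class MHABlock(Module):
    """Reference block: textbook multi-head attention in the same
    unfold/fold wrapper, for the ablation variant.

    Tokens run along the patch axis N with feature size C, batched over the
    within-patch position; quadratic cost in N.
    """

    def __init__(self, channels: int, num_heads: int = 4,
                 patch_shape: tuple[int, int] = (2, 2),
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % num_heads:
            raise ValueError(
                f"channels ({channels}) not divisible by heads ({num_heads})")
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.num_heads = num_heads
        self.patch_shape = tuple(patch_shape)
        self.qkv_map = Parameter(trunc_normal(rng, (channels, 3 * channels)))
        self.qkv_bias = Parameter(np.zeros(3 * channels))
        self.out_map = Parameter(trunc_normal(rng, (channels, channels)))
        self.out_bias = Parameter(np.zeros(channels))
        self.ffn = FeedForward(channels, "silu", rng=rng)

    def attend(self, x: Tensor) -> Tensor:
        """MHA over tokens on axis 2 of a (G, T, C) tensor."""
        G, T, C = x.shape
        h, d = self.num_heads, C // self.num_heads
        qkv = (x.reshape(G * T, C) @ self.qkv_map + self.qkv_bias)
        qkv = qkv.reshape(G, T, 3, h, d).transpose(2, 0, 3, 1, 4)  # (3,G,h,T,d)
        q3 = qkv.reshape(3, G * h, T, d)
        query, key, value = (_take3(q3, i) for i in range(3))
        attn = softmax((query @ key.transpose(0, 2, 1)) * (1.0 / np.sqrt(d)), axis=2)
        ctx = (attn @ value).reshape(G, h, T, d).transpose(0, 2, 1, 3).reshape(G, T, C)
        return (ctx.reshape(G * T, C) @ self.out_map + self.out_bias).reshape(G, T, C)

    def forward(self, x: Tensor) -> Tensor:
        X = unfold(x, self.patch_shape)
        B, C, P, N = X.data.shape
        tokens = X.data.transpose(0, 2, 3, 1).reshape(B * P, N, C)
        out = self.attend(channel_seq_norm(tokens))
        tokens = tokens + out
        seq = tokens.reshape(B, P, N, C).transpose(0, 3, 1, 2)
        A = PatchSequence(seq, X.patch_shape, X.origin_shape)
        z = self.ffn(PatchSequence(channel_layer_norm(A.data), A.patch_shape,
                                   A.origin_shape)).data
        return fold(PatchSequence(A.data + z, X.patch_shape, X.origin_shape))


def channel_seq_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Parameter-free layer norm over the last (feature) axis."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered ** 2.0).mean(axis=-1, keepdims=True)
    return centered / (var + eps).sqrt()


def _take3(x: Tensor, index: int) -> Tensor:
    """Select x[index] from the leading axis of length 3, differentiably."""
    mask = np.zeros((3,) + (1,) * (x.ndim - 1), dtype=x.dtype)
    mask[index] = 1.0
    return (x * Tensor(mask)).sum(axis=0)
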