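"""Independent brute-force oracles used by the test suite.

Everything here is written with explicit Python loops over indices, straight
from the mathematical definitions, deliberately sharing no code with the
implementation under test.
"""

from __future__ import annotations

import numpy as np


def unfold_oracle(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    """Index-by-index patch sequencing of a (B, C, H, W) array."""
    B, C, H, W = x.shape
    gw = W // pw
    P, N = ph * pw, (H // ph) * gw
    out = np.zeros((B, C, P, N), dtype=x.dtype)
    for b in range(B):
        for c in range(C):
            for p in range(P):
                for n in range(N):
                    row = (n // gw) * ph + p // pw
                    col = (n % gw) * pw + p % pw
                    out[b, c, p, n] = x[b, c, row, col]
    return out


def softmax_1d(v: np.ndarray) -> np.ndarray:
    e = np.exp(v - v.max())
    return e / e.sum()


def separable_attention_oracle(X: np.ndarray, w_i: np.ndarray,
                               w_k: np.ndarray, w_v: np.ndarray,
                               w_o: np.ndarray | None) -> np.ndarray:
    """Term-by-term separable self-attention with tokens along the last axis.

    ``X``: (B, C, P, N); weights act on the channel axis with the
    feature-in-first layout ``out[o] = sum_c X[c] * W[c, o]``.
    """
    B, C, P, N = X.shape
    out = np.zeros_like(X)
    for b in range(B):
        for p in range(P):
            scores = softmax_1d(np.array(
                [sum(X[b, c, p, n] * w_i[c, 0] for c in range(C))
                 for n in range(N)]))
            context = np.zeros(C)
            for o in range(C):
                for n in range(N):
                    key = sum(X[b, c, p, n] * w_k[c, o] for c in range(C))
                    context[o] += scores[n] * key
            for o in range(C):
                for n in range(N):
                    val = max(0.0, sum(X[b, c, p, n] * w_v[c, o]
                                       for c in range(C)))
                    out[b, o, p, n] = context[o] * val
    if w_o is None:
        return out
    projected = np.zeros_like(out)
    for b in range(B):
        for p in range(P):
            for n in range(N):
                for o2 in range(C):
                    projected[b, o2, p, n] = sum(
                        out[b, o, p, n] * w_o[o, o2] for o in range(C))
    return projected


def patch_attention_oracle(X: np.ndarray, w_i, w_k, w_v, w_o) -> np.ndarray:
    """Intra-patch branch: transpose P/N, attend over P, transpose back."""
    Xt = X.transpose(0, 1, 3, 2)
    Yt = separable_attention_oracle(Xt, w_i, w_k, w_v, w_o)
    return Yt.transpose(0, 1, 3, 2)


def ffn_oracle(X: np.ndarray, w1, b1, w2, activation: str | None) -> np.ndarray:
    """Dense position-wise FFN on the channel axis of (B, C, P, N)."""
    B, C, P, N = X.shape
    out = np.zeros_like(X)
    for b in range(B):
        for p in range(P):
            for n in range(N):
                vec = X[b, :, p, n]
                hidden = vec @ w1 + b1
                if activation == "silu":
                    hidden = hidden / (1.0 + np.exp(-hidden)) * 1.0
                    # silu(h) = h * sigmoid(h)
                    hidden = (vec @ w1 + b1)
                    hidden = hidden * (1.0 / (1.0 + np.exp(-hidden)))
                out[b, :, p, n] = hidden @ w2
    return out


def layer_norm_oracle(X: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Parameter-free normalization over the channel axis of (B, C, P, N)."""
    mu = X.mean(axis=1, keepdims=True)
    var = ((X - mu) ** 2).mean(axis=1, keepdims=True)
    return (X - mu) / np.sqrt(var + eps)


def lp_vit_block_oracle(x: np.ndarray, block) -> np.ndarray:
    """Scripted composition: unfold -> branches -> shared W_O -> FFN -> fold,
    reading the weights out of ``block`` but recomputing every stage with the
    loop oracles above."""
    ph, pw = block.patch_shape
    X = unfold_oracle(x, ph, pw)
    Xn = layer_norm_oracle(X) if block.use_norm else X
    left = separable_attention_oracle(
        Xn, block.inter_patch.context_projection.data,
        block.inter_patch.key_map.data, block.inter_patch.value_map.data,
        None)
    right = patch_attention_oracle(
        Xn, block.intra_patch.context_projection.data,
        block.intra_patch.key_map.data, block.intra_patch.value_map.data,
        None)
    fused = np.einsum("bcpn,cd->bdpn", left + right, block.output_map.data)
    if block.use_residual:
        fused = X + fused
    An = layer_norm_oracle(fused) if block.use_norm else fused
    z = ffn_oracle(An, block.ffn.expand_map.data, block.ffn.expand_bias.data,
                   block.ffn.project_map.data, block.ffn.activation)
    if block.use_residual:
        z = fused + z
    # fold = inverse permutation of unfold
    B, C, H, W = x.shape
    out = np.zeros_like(x)
    gw = W // pw
    for p in range(ph * pw):
        for n in range((H // ph) * gw):
            row = (n // gw) * ph + p // pw
            col = (n % gw) * pw + p % pw
            out[:, :, row, col] = z[:, :, p, n]
    return out


def mha_oracle(tokens: np.ndarray, w_qkv, b_qkv, w_out, b_out) -> np.ndarray:
    """Single-head textbook attention on (T, C) tokens."""
    T, C = tokens.shape
    qkv = tokens @ w_qkv + b_qkv
    q, k, v = qkv[:, :C], qkv[:, C:2 * C], qkv[:, 2 * C:]
    out = np.zeros_like(tokens)
    for t in range(T):
        scores = softmax_1d(np.array(
            [q[t] @ k[s] / np.sqrt(C) for s in range(T)]))
        ctx = sum(scores[s] * v[s] for s in range(T))
        out[t] = ctx @ w_out + b_out
    return out


def gradcam_linear_oracle(act: np.ndarray, head_w: np.ndarray,
                          target: int) -> np.ndarray:
    """Closed-form heatmap for a model: logits = GAP(act) @ head_w.

    d logit_k / d act[c, i, j] = head_w[c, k] / (h*w); the channel weights of
    the heatmap are therefore head_w[:, k] / (h*w).
    """
    C, h, w = act.shape
    weights = head_w[:, target] / (h * w)
    cam = np.maximum((weights[:, None, None] * act).sum(axis=0), 0.0)
    peak = cam.max()
    return cam / peak if peak > 0 else cam
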