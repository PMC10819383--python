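"""Equivalence of the separable-attention stages with explicit-loop oracles,
plus the structural properties of the LP-ViT block."""

import numpy as np
import pytest

from ehfrnet.attention import (FeedForward, LPViTBlock, MHABlock,
                               PatchAttention, SeparableSelfAttention)
from ehfrnet.nn.autograd import Tensor
from ehfrnet.patch_geometry import unfold

from oracles import (ffn_oracle, lp_vit_block_oracle, mha_oracle,
                     patch_attention_oracle, separable_attention_oracle)


def random_sequence(rng, B=1, C=3, P=4, N=2, H=None, W=None):
    # a sequence consistent with a (H, W) map for metadata purposes
    if H is None:
        H, W = 2 * 1, 2 * N  # P=4 -> 2x2 patches, N patches in a row
    return unfold(rng.normal(size=(B, C, H, W)), (2, 2))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_separable_attention_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    X = random_sequence(rng)
    attn = SeparableSelfAttention(3, rng=rng)
    got = attn(X).data.data
    want = separable_attention_oracle(
        X.data.data, attn.context_projection.data, attn.key_map.data,
        attn.value_map.data, attn.output_map.data)
    np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-7)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_patch_attention_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    X = random_sequence(rng)
    attn = PatchAttention(3, patch_len=4, rng=rng)
    got = attn(X).data.data
    want = patch_attention_oracle(
        X.data.data, attn.context_projection.data, attn.key_map.data,
        attn.value_map.data, attn.output_map.data)
    np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-7)


def test_zero_value_map_annihilates_output(rng):
    X = random_sequence(rng)
    attn = SeparableSelfAttention(3, rng=rng)
    attn.value_map.data[:] = 0
    assert not attn(X).data.data.any()


def test_singleton_token_axis_reduces_to_closed_form(rng):
    # one patch: N = 1, softmax over a single token is exactly 1
    X = unfold(rng.normal(size=(1, 3, 2, 2)), (2, 2))
    attn = SeparableSelfAttention(3, rng=rng)
    got = attn(X).data.data
    x = X.data.data
    key = np.einsum("bcpn,cd->bdpn", x, attn.key_map.data)
    val = np.maximum(np.einsum("bcpn,cd->bdpn", x, attn.value_map.data), 0)
    want = np.einsum("bcpn,cd->bdpn", key * val, attn.output_map.data)
    np.testing.assert_allclose(got, want, rtol=1e-6)


def test_degenerate_1x1_patches_use_singleton_softmax(rng):
    x = rng.normal(size=(1, 3, 2, 2))
    X = unfold(x, (1, 1))    # P = 1
    attn = PatchAttention(3, patch_len=1, rng=rng)
    got = attn(X).data.data
    want = patch_attention_oracle(
        X.data.data, attn.context_projection.data, attn.key_map.data,
        attn.value_map.data, attn.output_map.data)
    np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-7)


def test_permutation_equivariance_along_token_axis(rng):
    X = random_sequence(rng, N=5, W=10)
    attn = SeparableSelfAttention(3, rng=rng)
    perm = rng.permutation(5)
    base = attn(X).data.data
    from ehfrnet.patch_geometry import PatchSequence
    Xp = PatchSequence(Tensor(X.data.data[:, :, :, perm]), X.patch_shape,
                       X.origin_shape)
    permuted = attn(Xp).data.data
    np.testing.assert_allclose(permuted, base[:, :, :, perm], rtol=1e-5,
                               atol=1e-7)


def test_attention_scores_sum_to_one(rng):
    from ehfrnet.attention import _channel_linear
    from ehfrnet.nn.autograd import softmax
    X = random_sequence(rng, N=6, W=12)
    attn = SeparableSelfAttention(3, rng=rng)
    scores = softmax(_channel_linear(X.data, attn.context_projection),
                     axis=3).data
    np.testing.assert_allclose(scores.sum(axis=3), 1.0, atol=1e-6)


@pytest.mark.parametrize("activation", ["silu", None])
def test_ffn_matches_dense_oracle(rng, activation):
    X = random_sequence(rng)
    ffn = FeedForward(3, activation, rng=rng)
    got = ffn(X).data.data
    want = ffn_oracle(X.data.data, ffn.expand_map.data, ffn.expand_bias.data,
                      ffn.project_map.data, activation)
    np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-8)


def test_ffn_zero_weights_gives_zero(rng):
    X = random_sequence(rng)
    ffn = FeedForward(3, rng=rng)
    for p in ffn.parameters():
        p.data[:] = 0
    assert not ffn(X).data.data.any()


def test_ffn_identity_configuration(rng):
    # expand = [I; 0], project = [I, 0]^T, biases 0, literal affine mode
    ffn = FeedForward(3, activation=None, rng=rng)
    ffn.expand_map.data[:] = np.hstack([np.eye(3), np.zeros((3, 3))])
    ffn.expand_bias.data[:] = 0
    ffn.project_map.data[:] = np.vstack([np.eye(3), np.zeros((3, 3))])
    X = random_sequence(rng)
    np.testing.assert_allclose(ffn(X).data.data, X.data.data, atol=1e-7)


@pytest.mark.parametrize("seed", [0, 3])
def test_lp_vit_block_matches_composition_oracle(seed):
    rng = np.random.default_rng(seed)
    block = LPViTBlock(2, rng=rng)
    x = rng.normal(size=(1, 2, 4, 4))
    got = block(Tensor(x)).data
    want = lp_vit_block_oracle(x, block)
    np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-6)


def test_block_zero_weights_is_identity_through_residuals(rng):
    block = LPViTBlock(4, rng=rng)
    for p in block.parameters():
        p.data[:] = 0
    x = rng.normal(size=(2, 4, 4, 4))
    np.testing.assert_allclose(block(Tensor(x)).data, x, atol=1e-6)


def test_block_preserves_shape_at_canonical_size(rng):
    block = LPViTBlock(64, rng=rng)
    x = rng.normal(size=(1, 64, 64, 64)).astype(np.float32)
    out = block(Tensor(x))
    assert out.shape == x.shape
    assert np.isfinite(out.data).all()


def test_block_param_count_independent_of_resolution(rng):
    block = LPViTBlock(8, rng=rng)
    n_params = block.num_parameters()
    for size in (8, 32):
        out = block(Tensor(rng.normal(size=(1, 8, size, size))))
        assert out.shape == (1, 8, size, size)
    assert block.num_parameters() == n_params
    assert n_params == 9 * 8 * 8 + 4 * 8   # 9C^2 + 4C per block


def test_literal_patch_axis_mode_has_pxp_weights(rng):
    lit = PatchAttention(16, patch_len=4, weight_axis="patch", rng=rng)
    assert lit.key_map.shape == (4, 4)
    X = unfold(rng.normal(size=(1, 16, 4, 4)), (2, 2))
    assert lit(X).data.shape == (1, 16, 4, 4)


def test_mha_single_head_matches_textbook_oracle(rng):
    block = MHABlock(4, num_heads=1, rng=rng)
    tokens = rng.normal(size=(1, 2, 4))   # (G=1, T=2, C=4)
    got = block.attend(Tensor(tokens)).data[0]
    want = mha_oracle(tokens[0], block.qkv_map.data, block.qkv_bias.data,
                      block.out_map.data, block.out_bias.data)
    np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-7)


def test_mha_zero_value_projection_zeroes_attention(rng):
    block = MHABlock(4, num_heads=2, rng=rng)
    block.qkv_map.data[:, 8:] = 0     # value third of the fused projection
    block.qkv_bias.data[8:] = 0
    block.out_bias.data[:] = 0
    out = block.attend(Tensor(rng.normal(size=(2, 3, 4))))
    assert not out.data.any()


def test_mha_shape_contract_and_head_divisibility(rng):
    block = MHABlock(8, num_heads=4, rng=rng)
    x = rng.normal(size=(1, 8, 8, 8))
    assert block(Tensor(x)).shape == x.shape
    with pytest.raises(ValueError, match="divisible"):
        MHABlock(6, num_heads=4)
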