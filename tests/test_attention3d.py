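"""Windowed attention: round trips, masking, oracle equivalence, fusion."""

import numpy as np
import pytest

from getnet._tensor import Tensor
from getnet.attention3d import (
    FusionBlock,
    WindowAttention,
    convex_combine,
    cross_attention,
    cyclic_shift,
    fourier_positional_encoding,
    shift_attention_mask,
    swmsa,
    window_partition,
    window_reverse,
    wmsa,
)
from getnet.errors import ConfigurationError, ValidationError
from oracles import mha_oracle


@pytest.fixture()
def fmap(rng):
    return Tensor(rng.normal(size=(6, 4, 4, 4)))


def test_window_partition_reverse_round_trip(fmap):
    tokens = window_partition(fmap, (2, 2, 2))
    assert tokens.shape == (8, 8, 6)
    back = window_reverse(tokens, (2, 2, 2), (4, 4, 4))
    np.testing.assert_array_equal(back.numpy(), fmap.numpy())


def test_window_counts():
    x = Tensor(np.arange(8**3, dtype=float).reshape(1, 8, 8, 8))
    assert window_partition(x, (8, 8, 8)).shape[0] == 1
    assert window_partition(x, (4, 4, 4)).shape[0] == 8


def test_non_divisible_window_rejected(fmap):
    with pytest.raises(ValidationError):
        window_partition(fmap, (3, 2, 2))


def test_cyclic_shift_identities(fmap):
    assert cyclic_shift(fmap, (0, 0, 0)) is fmap
    rolled = cyclic_shift(fmap, (1, 2, 3))
    back = cyclic_shift(rolled, (-1, -2, -3))
    np.testing.assert_array_equal(back.numpy(), fmap.numpy())
    assert rolled.numpy().sum() == pytest.approx(fmap.numpy().sum())


def _make_attn(dim, heads, window, seed, relative_bias=True):
    return WindowAttention(dim, heads, window, np.random.default_rng(seed),
                           relative_bias=relative_bias)


def test_wmsa_matches_loop_oracle(rng):
    """Vectorized window attention equals the brute-force per-pair oracle."""
    for seed in range(20):
        attn = _make_attn(4, 2, (2, 2, 2), seed)
        x = Tensor(np.random.default_rng(100 + seed).normal(size=(4, 2, 2, 4)))
        out, k, v = wmsa(x, attn)
        tokens = window_partition(x, (2, 2, 2))
        q, k2, v2 = attn.project_qkv(tokens)
        bias = None
        if attn.relative_bias:
            flat = attn.bias_table.data[attn._bias_index.reshape(-1)]
            bias = flat.reshape(*attn._bias_index.shape, attn.num_heads)
            bias = bias.transpose(2, 0, 1)
        expected_tokens = mha_oracle(
            q.numpy(), k.numpy(), v.numpy(), attn.num_heads,
            attn.proj.weight.data, attn.proj.bias.data, bias=bias,
        )
        expected = window_reverse(Tensor(expected_tokens), (2, 2, 2), (2, 2, 4))
        np.testing.assert_allclose(out.numpy(), expected.numpy(), atol=1e-6)


def test_single_token_window_returns_projected_value(rng):
    attn = _make_attn(4, 1, (1, 1, 1), 0, relative_bias=False)
    x = Tensor(rng.normal(size=(4, 1, 1, 1)))
    out, _, v = wmsa(x, attn)
    expected = attn.proj(attn.merge_heads(v))
    np.testing.assert_allclose(
        out.numpy().reshape(-1), expected.numpy().reshape(-1), atol=1e-12
    )


def test_attention_rows_sum_to_one(fmap):
    attn = _make_attn(6, 2, (2, 2, 2), 3)
    *_, a = wmsa(fmap, attn, return_attn=True)
    np.testing.assert_allclose(a.numpy().sum(axis=-1), 1.0, atol=1e-6)
    *_, a = swmsa(fmap, attn, (1, 1, 1), return_attn=True)
    np.testing.assert_allclose(a.numpy().sum(axis=-1), 1.0, atol=1e-6)


def test_swmsa_zero_shift_equals_wmsa(fmap):
    attn = _make_attn(6, 2, (2, 2, 2), 5)
    out_w, k_w, v_w = wmsa(fmap, attn)
    out_s, k_s, v_s = swmsa(fmap, attn, (0, 0, 0))
    np.testing.assert_array_equal(out_w.numpy(), out_s.numpy())
    np.testing.assert_array_equal(k_w.numpy(), k_s.numpy())


def test_swmsa_masked_pairs_get_zero_weight(fmap):
    attn = _make_attn(6, 2, (2, 2, 2), 6)
    mask = shift_attention_mask((4, 4, 4), (2, 2, 2), (1, 1, 1))
    assert (mask < 0).any()
    *_, a = swmsa(fmap, attn, (1, 1, 1), return_attn=True)
    attn_np = a.numpy()  # (nW, heads, T, T)
    masked = np.broadcast_to(mask[:, None, :, :] < 0, attn_np.shape)
    assert np.abs(attn_np[masked]).max() < 1e-12


def test_swmsa_matches_pair_enumeration_oracle(rng):
    """Shifted attention equals an oracle that enumerates, for every query
    token of the shifted volume, exactly the keys from its own original
    region, computed in token space with loops."""
    attn = _make_attn(4, 1, (2, 2, 2), 9, relative_bias=False)
    x = Tensor(rng.normal(size=(4, 4, 4, 4)))
    shift = (1, 1, 1)
    out, *_ = swmsa(x, attn, shift)

    shifted = cyclic_shift(x, (-1, -1, -1))
    tokens = window_partition(shifted, (2, 2, 2))
    q, k, v = attn.project_qkv(tokens)
    mask = shift_attention_mask((4, 4, 4), (2, 2, 2), shift)
    expected_tokens = mha_oracle(
        q.numpy(), k.numpy(), v.numpy(), 1,
        attn.proj.weight.data, attn.proj.bias.data, mask=mask,
    )
    expected = cyclic_shift(
        window_reverse(Tensor(expected_tokens), (2, 2, 2), (4, 4, 4)), shift
    )
    np.testing.assert_allclose(out.numpy(), expected.numpy(), atol=1e-6)


def test_shift_not_smaller_than_window_rejected(fmap):
    attn = _make_attn(6, 2, (2, 2, 2), 7)
    with pytest.raises(ConfigurationError):
        swmsa(fmap, attn, (2, 1, 1))


def test_cross_attention_with_own_kv_equals_self_attention(fmap):
    attn = _make_attn(6, 2, (2, 2, 2), 8)
    out_self, k, v = wmsa(fmap, attn)
    out_cross = cross_attention(fmap, k, v, attn)
    np.testing.assert_allclose(out_cross.numpy(), out_self.numpy(), atol=1e-12)


def test_cross_attention_matches_loop_oracle(rng):
    attn = _make_attn(4, 2, (2, 2, 2), 10)
    x = Tensor(rng.normal(size=(4, 2, 2, 2)))
    enc = Tensor(rng.normal(size=(4, 2, 2, 2)))
    _, bk, bv = wmsa(enc, attn)
    out = cross_attention(x, bk, bv, attn)
    tokens = window_partition(x, (2, 2, 2))
    q, _, _ = attn.project_qkv(tokens)
    bias = attn.bias_table.data[attn._bias_index.reshape(-1)]
    bias = bias.reshape(*attn._bias_index.shape, attn.num_heads).transpose(2, 0, 1)
    expected_tokens = mha_oracle(
        q.numpy(), bk.numpy(), bv.numpy(), 2,
        attn.proj.weight.data, attn.proj.bias.data, bias=bias,
    )
    expected = window_reverse(Tensor(expected_tokens), (2, 2, 2), (2, 2, 2))
    np.testing.assert_allclose(out.numpy(), expected.numpy(), atol=1e-6)


def test_cross_attention_stage_mismatch_rejected(fmap):
    attn = _make_attn(6, 2, (2, 2, 2), 11)
    _, k, v = wmsa(fmap, attn)
    bad_k = Tensor(k.numpy()[:4])  # wrong window count
    with pytest.raises(ValidationError):
        cross_attention(fmap, bad_k, v, attn)


# ---------------------------------------------------------------------------
# positional encoding and fusion


def test_fpe_position_zero_and_range():
    pe = fourier_positional_encoding(16, 8, 10_000.0)
    np.testing.assert_array_equal(pe[0, 0::2], 0.0)  # sin 0
    np.testing.assert_array_equal(pe[0, 1::2], 1.0)  # cos 0
    assert (np.abs(pe) <= 1.0).all()


def test_fpe_lowest_channel_invariant_to_frequency():
    a = fourier_positional_encoding(8, 6, 10_000.0)
    b = fourier_positional_encoding(8, 6, 20_000.0)
    np.testing.assert_allclose(a[:, :2], b[:, :2], atol=1e-15)
    assert not np.allclose(a[:, 2:], b[:, 2:])


def test_fpe_odd_dim_rejected():
    with pytest.raises(ConfigurationError):
        fourier_positional_encoding(4, 5)


def test_convex_combination_endpoints_and_midpoint(rng):
    ca = Tensor(rng.normal(size=(2, 8, 4)))
    sa = Tensor(rng.normal(size=(2, 8, 4)))
    np.testing.assert_array_equal(convex_combine(ca, sa, 1.0).numpy(), sa.numpy())
    np.testing.assert_array_equal(convex_combine(ca, sa, 0.0).numpy(), ca.numpy())
    np.testing.assert_allclose(
        convex_combine(sa, sa, 0.5).numpy(), sa.numpy(), atol=1e-15
    )
    mid = convex_combine(ca, sa, 0.5).numpy()
    np.testing.assert_allclose(mid, 0.5 * (ca.numpy() + sa.numpy()), atol=1e-15)


def test_fusion_block_default_balances_branches(rng):
    fuse = FusionBlock(4, 8, rng)
    assert fuse.lam == 0.5
    ca = Tensor(rng.normal(size=(2, 8, 4)))
    sa = Tensor(rng.normal(size=(2, 8, 4)))
    out = fuse(ca, sa)
    assert out.shape == (2, 8, 4)
    # fusion of equal branches reduces to z + FPE + MLP path on z
    same = fuse(sa, sa)
    z = sa + Tensor(fuse.fpe)
    expected = z + fuse.mlp(fuse.norm(z))
    np.testing.assert_allclose(same.numpy(), expected.numpy(), atol=1e-12)
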