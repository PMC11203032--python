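"""3D windowed self-attention machinery.

The encoder/decoder transformer blocks operate on non-overlapping 3D
windows of the token grid (W-MSA).  Alternating layers shift the grid
cyclically by half a window (SW-MSA) so information can flow between
neighbouring windows; tokens that become adjacent only through the wrap-
around are prevented from attending to each other by an additive mask.
Decoder layers additionally run cross-attention, with queries from the
decoder and key/value pairs bridged over from the matching encoder layer
(the volumetric-transformer analogue of a U-Net skip connection); the
self- and cross-attention outputs are merged by a convex combination
followed by Fourier positional encoding, layer norm and an MLP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import LayerNorm, Linear, Mlp, Module, Parameter
from ._tensor import Tensor
from .errors import ConfigurationError, ValidationError

__all__ = [
    "AttentionKV",
    "window_partition",
    "window_reverse",
    "cyclic_shift",
    "shift_attention_mask",
    "WindowAttention",
    "wmsa",
    "swmsa",
    "cross_attention",
    "fourier_positional_encoding",
    "FusionBlock",
    "convex_combine",
]

_NEG = -1e9  # additive mask value: attention weight underflows to exactly 0


@dataclass
class AttentionKV:
    """Key/value pairs cached by an encoder layer for the decoder bridge.

    ``k``/``v`` come from the un-shifted (W-MSA) sub-layer, ``k_shift``/
    ``v_shift`` from the shifted (SW-MSA) sub-layer.  All are shaped
    ``(n_windows, heads, tokens, head_dim)``.
    """

    k: Tensor | None = None
    v: Tensor | None = None
    k_shift: Tensor | None = None
    v_shift: Tensor | None = None
    #: number of decoder blocks that consumed this cache
    consumed: int = 0


# ---------------------------------------------------------------------------
# window bookkeeping


def window_partition(x: Tensor, win: tuple[int, int, int]) -> Tensor:
    """(C, D, H, W) -> (n_windows, wd*wh*ww, C) window tokens."""
    c, d, h, w = x.shape
    wd, wh, ww = win
    if d % wd or h % wh or w % ww:
        raise ValidationError(f"spatial dims {(d, h, w)} not divisible by {win}")
    x = x.reshape(c, d // wd, wd, h // wh, wh, w // ww, ww)
    x = x.transpose(1, 3, 5, 2, 4, 6, 0)
    return x.reshape((d // wd) * (h // wh) * (w // ww), wd * wh * ww, c)


def window_reverse(
    tokens: Tensor, win: tuple[int, int, int], spatial: tuple[int, int, int]
) -> Tensor:
    """Inverse of :func:`window_partition`."""
    d, h, w = spatial
    wd, wh, ww = win
    c = tokens.shape[-1]
    x = tokens.reshape(d // wd, h // wh, w // ww, wd, wh, ww, c)
    x = x.transpose(6, 0, 3, 1, 4, 2, 5)
    return x.reshape(c, d, h, w)


def cyclic_shift(x: Tensor, shift: tuple[int, int, int]) -> Tensor:
    """Circular roll of the spatial axes; ``-shift`` is the exact inverse."""
    if not any(shift):
        return x
    return x.roll(shift, axis=(1, 2, 3))


def shift_attention_mask(
    spatial: tuple[int, int, int], win: tuple[int, int, int], shift: tuple[int, int, int]
) -> np.ndarray | None:
    """Additive attention mask for shifted windows.

    After a cyclic shift, a window may gather tokens from up to eight
    disconnected regions of the original volume; pairs from different
    regions get a large negative additive bias.  Returns an array of
    shape ``(n_windows, T, T)`` (zeros and ``-1e9``), or None when the
    shift is zero.
    """
    if not any(shift):
        return None
    region = np.zeros(spatial)
    cnt = 0
    slabs = []
    for s, wn, sh in zip(spatial, win, shift):
        slabs.append((slice(0, s - wn), slice(s - wn, s - sh), slice(s - sh, s)))
    for sd in slabs[0]:
        for sh_ in slabs[1]:
            for sw in slabs[2]:
                region[sd, sh_, sw] = cnt
                cnt += 1
    shifted = np.roll(region, tuple(-s for s in shift), axis=(0, 1, 2))
    ids = window_partition(Tensor(shifted[None]), win).numpy()[:, :, 0]
    diff = ids[:, :, None] != ids[:, None, :]
    return np.where(diff, _NEG, 0.0)


# ---------------------------------------------------------------------------
# attention


class WindowAttention(Module):
    """Multi-head scaled-dot-product attention within windows.

    Holds the QKV and output projections plus (optionally) a learned 3D
    relative position bias indexed by the offset between token positions
    inside the window, following the hierarchical-window lineage.
    """

    def __init__(
        self,
        dim: int,
        num_heads: int,
        window_size: tuple[int, int, int],
        rng: np.random.Generator,
        relative_bias: bool = True,
    ):
        super().__init__()
        if dim % num_heads:
            raise ConfigurationError(f"heads {num_heads} must divide dim {dim}")
        self.dim = dim
        self.num_heads = num_heads
        self.window_size = tuple(window_size)
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.relative_bias = relative_bias
        if relative_bias:
            wd, wh, ww = self.window_size
            table_size = (2 * wd - 1) * (2 * wh - 1) * (2 * ww - 1)
            self.bias_table = Parameter(
                rng.normal(0.0, 0.02, (table_size, num_heads))
            )
            coords = np.stack(
                np.meshgrid(
                    np.arange(wd), np.arange(wh), np.arange(ww), indexing="ij"
                )
            ).reshape(3, -1)
            rel = coords[:, :, None] - coords[:, None, :]
            rel = rel + np.array([wd - 1, wh - 1, ww - 1])[:, None, None]
            index = (
                rel[0] * (2 * wh - 1) * (2 * ww - 1) + rel[1] * (2 * ww - 1) + rel[2]
            )
            self._bias_index = index.astype(np.intp)  # (T, T), constant

    # -- projections

    def split_heads(self, t: Tensor) -> Tensor:
        """(nW, T, C) -> (nW, heads, T, C/heads)"""
        nw, tk, c = t.shape
        hd = c // self.num_heads
        return t.reshape(nw, tk, self.num_heads, hd).transpose(0, 2, 1, 3)

    def merge_heads(self, t: Tensor) -> Tensor:
        nw, nh, tk, hd = t.shape
        return t.transpose(0, 2, 1, 3).reshape(nw, tk, nh * hd)

    def project_qkv(self, tokens: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        c = self.dim
        qkv = self.qkv(tokens)
        q = self.split_heads(qkv[:, :, :c])
        k = self.split_heads(qkv[:, :, c : 2 * c])
        v = self.split_heads(qkv[:, :, 2 * c :])
        return q, k, v

    # -- core

    def attend(
        self,
        q: Tensor,
        k: Tensor,
        v: Tensor,
        mask: np.ndarray | None = None,
        return_attn: bool = False,
    ):
        """Scaled-dot-product attention on per-head tokens.

        ``q, k, v`` are ``(nW, heads, T, head_dim)``; ``mask`` is an
        additive ``(nW, T, T)`` bias applied before the softmax.
        """
        hd = q.shape[-1]
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        if self.relative_bias and k.shape[2] == self._bias_index.shape[0]:
            bias = self.bias_table[self._bias_index.reshape(-1)]
            bias = bias.reshape(*self._bias_index.shape, self.num_heads)
            scores = scores + bias.transpose(2, 0, 1)
        if mask is not None:
            scores = scores + Tensor(mask[:, None, :, :])
        attn = scores.softmax(axis=-1)
        out = self.proj(self.merge_heads(attn @ v))
        if return_attn:
            return out, attn
        return out


def wmsa(
    x: Tensor,
    weights: WindowAttention,
    mask: np.ndarray | None = None,
    return_attn: bool = False,
):
    """Window multi-head self-attention on a (C, D, H, W) feature map.

    Returns ``(out, k, v)`` (plus the attention array when requested);
    ``k``/``v`` feed the encoder→decoder bridge.
    """
    spatial = x.shape[1:]
    tokens = window_partition(x, weights.window_size)
    q, k, v = weights.project_qkv(tokens)
    res = weights.attend(q, k, v, mask=mask, return_attn=return_attn)
    if return_attn:
        out_tokens, attn = res
    else:
        out_tokens = res
    out = window_reverse(out_tokens, weights.window_size, spatial)
    if return_attn:
        return out, k, v, attn
    return out, k, v


def swmsa(
    x: Tensor,
    weights: WindowAttention,
    shift: tuple[int, int, int],
    return_attn: bool = False,
):
    """Shifted-window attention: cyclic shift → masked W-MSA → inverse shift."""
    if any(s >= w for s, w in zip(shift, weights.window_size)):
        raise ConfigurationError(f"shift {shift} must be < window {weights.window_size}")
    spatial = x.shape[1:]
    shifted = cyclic_shift(x, tuple(-s for s in shift))
    mask = shift_attention_mask(spatial, weights.window_size, shift)
    res = wmsa(shifted, weights, mask=mask, return_attn=return_attn)
    if return_attn:
        out, k, v, attn = res
    else:
        out, k, v = res
    out = cyclic_shift(out, shift)
    if return_attn:
        return out, k, v, attn
    return out, k, v


def cross_attention(
    x: Tensor,
    bridged_k: Tensor,
    bridged_v: Tensor,
    weights: WindowAttention,
    shift: tuple[int, int, int] = (0, 0, 0),
    mask: np.ndarray | None = None,
) -> Tensor:
    """Attention with decoder queries against encoder keys/values.

    ``x`` is the decoder feature map; queries are produced by ``weights``'
    own projection while ``bridged_k``/``bridged_v`` come from the
    matching encoder layer.  With ``bridged_k``/``bridged_v`` equal to
    the decoder's own projections this reduces to self-attention.
    """
    spatial = x.shape[1:]
    shifted = cyclic_shift(x, tuple(-s for s in shift)) if any(shift) else x
    tokens = window_partition(shifted, weights.window_size)
    q, _, _ = weights.project_qkv(tokens)
    if bridged_k.shape != q.shape or bridged_v.shape != q.shape:
        raise ValidationError(
            f"bridged K/V shape {bridged_k.shape} incompatible with queries {q.shape}"
        )
    if mask is None and any(shift):
        mask = shift_attention_mask(spatial, weights.window_size, shift)
    out_tokens = weights.attend(q, bridged_k, bridged_v, mask=mask)
    out = window_reverse(out_tokens, weights.window_size, spatial)
    if any(shift):
        out = cyclic_shift(out, shift)
    return out


# ---------------------------------------------------------------------------
# positional encoding and CA/SA fusion


def fourier_positional_encoding(
    n_positions: int, dim: int, freq: float = 10_000.0
) -> np.ndarray:
    """Sinusoidal position code with a geometric wavelength progression.

    ``pe[p, 2i] = sin(p / freq^(2i/dim))``, ``pe[p, 2i+1] = cos(...)``;
    wavelengths run geometrically from 2π up to ``freq``·2π.
    """
    if dim % 2:
        raise ConfigurationError("encoding dim must be even")
    if freq <= 0:
        raise ConfigurationError("freq must be positive")
    pos = np.arange(n_positions)[:, None]
    i = np.arange(dim // 2)[None, :]
    angle = pos / freq ** (2.0 * i / dim)
    pe = np.zeros((n_positions, dim))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def convex_combine(ca_out: Tensor, sa_out: Tensor, lam: float) -> Tensor:
    """``(1 − λ)·ca + λ·sa`` — λ weights the self-attention branch."""
    if ca_out.shape != sa_out.shape:
        raise ValidationError(
            f"branch shapes differ: {ca_out.shape} vs {sa_out.shape}"
        )
    if not 0.0 <= lam <= 1.0:
        raise ConfigurationError("lambda must lie in [0, 1]")
    if lam == 0.0:
        return ca_out
    if lam == 1.0:
        return sa_out
    return ca_out * (1.0 - lam) + sa_out * lam


class FusionBlock(Module):
    """Merge cross- and self-attention: convex combination → +FPE → LN → MLP.

    The convex weight λ multiplies the self-attention branch (default
    0.5, the balanced setting); the Fourier code is added per token
    position inside the window, and the residual spans the LN + MLP pair.
    """

    def __init__(
        self,
        dim: int,
        n_tokens: int,
        rng: np.random.Generator,
        lam: float = 0.5,
        freq: float = 10_000.0,
        mlp_ratio: float = 2.0,
    ):
        super().__init__()
        if not 0.0 <= lam <= 1.0:
            raise ConfigurationError("lambda must lie in [0, 1]")
        self.lam = lam
        self.fpe = fourier_positional_encoding(n_tokens, dim, freq)  # constant
        self.norm = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)

    def forward(self, ca_tokens: Tensor, sa_tokens: Tensor) -> Tensor:
        y = convex_combine(ca_tokens, sa_tokens, self.lam)
        z = y + Tensor(self.fpe)
        return z + self.mlp(self.norm(z))
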