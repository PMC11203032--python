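"""Enhanced Channel Self-Attention (ECSA) and its transformer wrapper.

The ECSA block lives in the bottleneck, where feature maps are smallest
but semantically richest.  It proceeds in three steps:

1. *weights* — three per-channel gate vectors are squeezed out of the
   features by global average pooling followed by a two-layer bottleneck
   (``sigmoid(FL(ReLU(FL(AP(·)))))``): Q and K gates from linearly
   projected features, the V gate from the raw features;
2. *weighted global features* — the gates scale their respective feature
   tensors channel-wise (Q′, K′, V′);
3. *local fusion* — the Hadamard product K′ ⊙ Q′ passes through a
   large-kernel (7×7×7) depth-wise convolution for local context, a
   1×1×1 channel-aggregation convolution and a channel softmax, and the
   result gates V′ before a final linear output map.

The Enhanced Transformer wraps ECSA in the standard pre-norm residual
pair: ``y = ECSA(LN(x)) + x``, ``z = y + MLP(LN(y))``.
"""

from __future__ import annotations

import numpy as np

from ._nn import Conv1x1x1, DepthwiseConv3d, LayerNorm, Linear, Mlp, Module
from ._tensor import Tensor
from .errors import ConfigurationError

__all__ = ["ChannelGate", "EcsaBlock", "EnhancedTransformer", "channel_gate"]


class ChannelGate(Module):
    """Squeeze-style per-channel gate: sigmoid(FL(ReLU(FL(AP(x))))).

    AP is global spatial average pooling; both linear maps are square
    (C → C).  The output is a length-C vector with entries in (0, 1),
    and depends on the input only through its spatial average — it is
    invariant to any permutation of spatial positions.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(channels, channels, rng)
        self.fc2 = Linear(channels, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(1, 2, 3))  # (C,)
        return self.fc2(self.fc1(pooled).relu()).sigmoid()


def channel_gate(x: Tensor, gate: ChannelGate) -> Tensor:
    """Functional form of :class:`ChannelGate`."""
    return gate(x)


def _ln_channels(x: Tensor, norm: LayerNorm) -> Tensor:
    """LayerNorm over the channel axis of a (C, D, H, W) map."""
    return norm(x.transpose(1, 2, 3, 0)).transpose(3, 0, 1, 2)


class EcsaBlock(Module):
    """The enhanced channel self-attention block; shape-preserving."""

    def __init__(
        self,
        channels: int,
        rng: np.random.Generator,
        dwc_kernel: int = 7,
        softmax_axis: int = 0,
    ):
        super().__init__()
        self.channels = channels
        self.softmax_axis = softmax_axis
        # linear (1×1×1) maps for the Q/K paths and the output
        self.fl_q = Conv1x1x1(channels, channels, rng)
        self.fl_k = Conv1x1x1(channels, channels, rng)
        self.fl_out = Conv1x1x1(channels, channels, rng)
        # independent gates: F_SW for Q and K (on projected features),
        # F_W for V (on the raw features)
        self.gate_q = ChannelGate(channels, rng)
        self.gate_k = ChannelGate(channels, rng)
        self.gate_v = ChannelGate(channels, rng)
        self.dwc = DepthwiseConv3d(channels, dwc_kernel, rng)
        self.conv = Conv1x1x1(channels, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[0] != self.channels:
            raise ConfigurationError(
                f"expected {self.channels} channels, got {x.shape[0]}"
            )
        c = self.channels
        flx_q = self.fl_q(x)
        flx_k = self.fl_k(x)
        qw = self.gate_q(flx_q)
        kw = self.gate_k(flx_k)
        vw = self.gate_v(x)
        q = flx_q * qw.reshape(c, 1, 1, 1)
        k = flx_k * kw.reshape(c, 1, 1, 1)
        v = x * vw.reshape(c, 1, 1, 1)
        local = self.conv(self.dwc(k * q))
        attn = local.softmax(axis=self.softmax_axis)
        return self.fl_out(attn * v)


class EnhancedTransformer(Module):
    """Pre-norm residual wrapper around :class:`EcsaBlock`.

    ``y = ECSA(LN(x)) + x`` then ``z = y + MLP(LN(y))``, with LayerNorm
    and the MLP acting on the channel vector at every voxel.
    """

    def __init__(
        self,
        channels: int,
        rng: np.random.Generator,
        dwc_kernel: int = 7,
        mlp_ratio: float = 2.0,
        softmax_axis: int = 0,
    ):
        super().__init__()
        self.norm1 = LayerNorm(channels)
        self.ecsa = EcsaBlock(channels, rng, dwc_kernel, softmax_axis)
        self.norm2 = LayerNorm(channels)
        self.mlp = Mlp(channels, int(channels * mlp_ratio), rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.ecsa(_ln_channels(x, self.norm1)) + x
        c, d, h, w = y.shape
        tokens = y.transpose(1, 2, 3, 0)
        z = tokens + self.mlp(self.norm2(tokens))
        return z.transpose(3, 0, 1, 2)
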