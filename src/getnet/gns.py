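"""Group-Normalization-Shuffle (GNS) block.

A ShuffleNetV2-style unit adapted for segmentation: the channels are
split into two halves; the left half passes through untouched while the
right half runs a 1×1×1 conv → depth-wise 3×3×3 conv → 1×1×1 conv
pipeline; the halves are concatenated and a channel shuffle mixes them.
Where ShuffleNetV2 used batch norm and ReLU, this block uses group
normalization (batch-size independent, which matters at batch size 1)
and GeLU, in the layout found best by ablation: GN+GeLU after the first
pointwise conv, plain GN after the depth-wise conv, GN+GeLU after the
second pointwise conv.  The original BN+ReLU layout and the other
normalization/activation placements remain available via ``layout``.

One GNS block sits after the transformer encoder block at every encoder
stage, before patch merging.
"""

from __future__ import annotations

import numpy as np

from ._nn import Conv1x1x1, DepthwiseConv3d, Module, Parameter
from ._tensor import Tensor, concat
from .errors import ValidationError

__all__ = [
    "channel_split",
    "channel_shuffle",
    "GroupNorm",
    "group_normalize",
    "GnsBlock",
    "UNIT_LAYOUTS",
    "default_gn_groups",
]

#: normalization/activation per unit position for each ablation layout
UNIT_LAYOUTS = {
    "A": (("BN", "relu"), ("BN", None), ("BN", "relu")),
    "B": (("GN", "gelu"), ("GN", "gelu"), ("GN", "gelu")),
    "C": (("GN", None), ("GN", None), ("GN", None)),
    "D": (("GN", None), ("GN", "gelu"), ("GN", None)),
    "E": (("GN", "gelu"), ("GN", None), ("GN", "gelu")),
}


def channel_split(x: Tensor) -> tuple[Tensor, Tensor]:
    """Split (C, D, H, W) into the first and last C/2 channels."""
    c = x.shape[0]
    if c % 2:
        raise ValidationError(f"channel count {c} must be even to split")
    return x[: c // 2], x[c // 2 :]


def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    """The group-transpose channel permutation; spatial content untouched."""
    c = x.shape[0]
    if c % groups:
        raise ValidationError(f"groups {groups} must divide channels {c}")
    rest = x.shape[1:]
    return (
        x.reshape(groups, c // groups, *rest)
        .transpose(1, 0, 2, 3, 4)
        .reshape(c, *rest)
    )


def default_gn_groups(channels: int, cap: int = 8) -> int:
    """Largest divisor of ``channels`` not exceeding ``cap``."""
    for g in range(min(cap, channels), 0, -1):
        if channels % g == 0:
            return g
    return 1


class GroupNorm(Module):
    """Group normalization with per-channel affine.

    Mean and variance are computed per channel group over all voxels of
    the single sample, so the result is independent of batching.
    """

    def __init__(self, channels: int, groups: int, eps: float = 1e-5):
        super().__init__()
        if channels % groups:
            raise ValidationError(f"groups {groups} must divide channels {channels}")
        self.groups = groups
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[0]
        rest = x.shape[1:]
        g = self.groups
        xg = x.reshape(g, -1)
        mu = xg.mean(axis=1, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        normed = (xc / (var + self.eps).sqrt()).reshape(c, *rest)
        shape = (c,) + (1,) * len(rest)
        return normed * self.gamma.reshape(shape) + self.beta.reshape(shape)


def group_normalize(x: Tensor, norm: GroupNorm) -> Tensor:
    """Functional form of :class:`GroupNorm`."""
    return norm(x)


class _InstanceBatchNorm(Module):
    """Per-channel normalization over the sample's voxels (the batch-size-1
    specialization of training-mode batch norm), used by the legacy 'A'
    layout."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[0]
        rest = x.shape[1:]
        xf = x.reshape(c, -1)
        mu = xf.mean(axis=1, keepdims=True)
        xc = xf - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        normed = (xc / (var + self.eps).sqrt()).reshape(c, *rest)
        shape = (c,) + (1,) * len(rest)
        return normed * self.gamma.reshape(shape) + self.beta.reshape(shape)


class _Unit(Module):
    """One normalization(+activation) unit of the GNS pipeline."""

    def __init__(self, channels: int, kind: str, activation: str | None, gn_groups: int):
        super().__init__()
        if kind == "GN":
            self.norm = GroupNorm(channels, gn_groups)
        elif kind == "BN":
            self.norm = _InstanceBatchNorm(channels)
        else:  # pragma: no cover
            raise ValueError(kind)
        self.activation = activation

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm(x)
        if self.activation == "gelu":
            return x.gelu()
        if self.activation == "relu":
            return x.relu()
        return x


class GnsBlock(Module):
    """Split → (identity | conv/DWC/conv with three units) → concat → shuffle."""

    def __init__(
        self,
        channels: int,
        rng: np.random.Generator,
        layout: str = "E",
        gn_groups: int | None = None,
        shuffle_groups: int = 2,
    ):
        super().__init__()
        if channels % 2:
            raise ValidationError(f"channel count {channels} must be even")
        branch = channels // 2
        if gn_groups is None:
            gn_groups = default_gn_groups(branch)
        if layout not in UNIT_LAYOUTS:
            raise ValidationError(f"unknown unit layout {layout!r}")
        units = UNIT_LAYOUTS[layout]
        self.shuffle_groups = shuffle_groups
        self.conv1 = Conv1x1x1(branch, branch, rng)
        self.unit1 = _Unit(branch, *units[0], gn_groups)
        self.dwc = DepthwiseConv3d(branch, 3, rng)
        self.unit2 = _Unit(branch, *units[1], gn_groups)
        self.conv2 = Conv1x1x1(branch, branch, rng)
        self.unit3 = _Unit(branch, *units[2], gn_groups)

    def forward(self, x: Tensor) -> Tensor:
        left, right = channel_split(x)
        right = self.unit1(self.conv1(right))
        right = self.unit2(self.dwc(right))
        right = self.unit3(self.conv2(right))
        return channel_shuffle(concat([left, right], axis=0), self.shuffle_groups)
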