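"""The GETNet segmentation network.

A U-shaped volumetric transformer: the input volume is cut into
non-overlapping patches and linearly embedded; encoder stages alternate
windowed and shifted-window attention, each followed by a GNS block and
a patch-merging downsample; a two-layer enhanced-channel-self-attention
bottleneck sits at the bottom; decoder stages mirror the encoder with
parallel self- and cross-attention (keys/values bridged from the
matching encoder layer) merged by a convex-combination fusion block, and
patch-expanding upsamples; a final expansion and a 1×1×1 convolution
produce one logit channel per evaluated region (WT, TC, ET).

Patch merging here halves depth as well as height/width (each merge
trades 8 voxels for a doubling of channels); the fixed-depth variant of
the baseline volumetric transformer (which halves only height/width) is
kept behind ``depth_halving=False``, and :func:`count_macs` shows the
depth-halving layout needs strictly fewer multiply–accumulates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._nn import Conv1x1x1, LayerNorm, Linear, Mlp, Module, ModuleList
from ._tensor import Tensor
from .attention3d import (
    AttentionKV,
    FusionBlock,
    WindowAttention,
    cyclic_shift,
    shift_attention_mask,
    swmsa,
    window_partition,
    window_reverse,
    wmsa,
)
from .bratsio import RegionMask, SegmentationMask, regions_to_labels
from .ecsa import EnhancedTransformer
from .errors import ConfigurationError, ValidationError
from .gns import GnsBlock

__all__ = [
    "ModelConfig",
    "MacCount",
    "GETNet",
    "PatchEmbed",
    "PatchMerge",
    "PatchExpand",
    "count_macs",
    "predict_labels",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    Defaults give a toy profile that trains on a CPU at 32³ input; the
    architecture itself is scale-free and the same code runs a 128³
    configuration by raising ``embed_dim``/``depths``.
    """

    in_channels: int = 4
    out_channels: int = 3
    patch_size: int = 4
    embed_dim: int = 8
    depths: tuple[int, ...] = (2, 2)  # VT blocks per encoder/decoder stage
    heads: tuple[int, ...] = (2, 4)
    window_size: tuple[int, int, int] = (2, 2, 2)
    lam: float = 0.5  # convex weight of the self-attention branch
    fpe_freq: float = 10_000.0
    gns_layout: str = "E"
    gn_groups: int | None = None
    bottleneck_depth: int = 2
    dwc_kernel: int = 7
    depth_halving: bool = True
    relative_bias: bool = True
    mlp_ratio: float = 2.0

    @property
    def n_stages(self) -> int:
        return len(self.depths)

    @property
    def shift_size(self) -> tuple[int, int, int]:
        return tuple(w // 2 for w in self.window_size)

    def stage_dim(self, stage: int) -> int:
        return self.embed_dim * 2**stage

    def validate(self) -> None:
        if len(self.depths) != len(self.heads):
            raise ConfigurationError("depths and heads must have equal length")
        if not 0.0 <= self.lam <= 1.0:
            raise ConfigurationError("lambda must lie in [0, 1]")
        for i, h in enumerate(self.heads):
            if self.stage_dim(i) % h:
                raise ConfigurationError(
                    f"heads {h} must divide stage dim {self.stage_dim(i)}"
                )
        if any(s >= w for s, w in zip(self.shift_size, self.window_size)):
            raise ConfigurationError("shift must be smaller than window")

    def stage_grids(self, spatial: tuple[int, int, int]) -> list[tuple[int, int, int]]:
        """Token-grid shape per stage (index 0..n_stages) incl. bottleneck."""
        p = self.patch_size
        if any(s % p for s in spatial):
            raise ConfigurationError(f"input {spatial} not divisible by patch {p}")
        grid = tuple(s // p for s in spatial)
        grids = [grid]
        for _ in range(self.n_stages):
            d, h, w = grids[-1]
            if (self.depth_halving and d % 2) or h % 2 or w % 2:
                raise ConfigurationError(f"grid {grids[-1]} has odd merge axes")
            grids.append(((d // 2 if self.depth_halving else d), h // 2, w // 2))
        for grid in grids[:-1]:
            if any(g % w for g, w in zip(grid, self.window_size)):
                raise ConfigurationError(
                    f"window {self.window_size} does not divide token grid {grid}"
                )
        return grids


# ---------------------------------------------------------------------------
# patch resampling blocks


def _to_tokens(x: Tensor) -> Tensor:
    """(C, D, H, W) -> (D, H, W, C)."""
    return x.transpose(1, 2, 3, 0)


def _to_map(x: Tensor) -> Tensor:
    """(D, H, W, C) -> (C, D, H, W)."""
    return x.transpose(3, 0, 1, 2)


class PatchEmbed(Module):
    """Non-overlapping patch flattening + linear projection + LayerNorm."""

    def __init__(self, in_channels: int, patch_size: int, dim: int, rng):
        super().__init__()
        self.patch_size = patch_size
        self.proj = Linear(in_channels * patch_size**3, dim, rng)
        self.norm = LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        c, d, h, w = x.shape
        p = self.patch_size
        if d % p or h % p or w % p:
            raise ValidationError(f"spatial dims {(d, h, w)} not divisible by {p}")
        x = x.reshape(c, d // p, p, h // p, p, w // p, p)
        x = x.transpose(1, 3, 5, 0, 2, 4, 6).reshape(d // p, h // p, w // p, c * p**3)
        return _to_map(self.norm(self.proj(x)))


class PatchMerge(Module):
    """Neighbourhood concatenation + linear reduction to 2C channels.

    With ``depth_halving`` all three axes halve (8-voxel neighbourhood);
    otherwise depth is kept (4-voxel neighbourhood), as in the baseline.
    """

    def __init__(self, dim: int, depth_halving: bool, rng):
        super().__init__()
        self.fd = 2 if depth_halving else 1
        n = self.fd * 4
        self.norm = LayerNorm(n * dim)
        self.reduce = Linear(n * dim, 2 * dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        c, d, h, w = x.shape
        fd = self.fd
        if d % fd or h % 2 or w % 2:
            raise ValidationError(f"odd merge axis in {(d, h, w)}")
        x = x.reshape(c, d // fd, fd, h // 2, 2, w // 2, 2)
        x = x.transpose(1, 3, 5, 2, 4, 6, 0)
        x = x.reshape(d // fd, h // 2, w // 2, fd * 4 * c)
        return _to_map(self.reduce(self.norm(x)))


class PatchExpand(Module):
    """Linear expansion + spatial rearrangement; inverse shape of merging."""

    def __init__(self, dim: int, depth_halving: bool, rng):
        super().__init__()
        if dim % 2:
            raise ValidationError(f"channel count {dim} must be even to expand")
        self.fd = 2 if depth_halving else 1
        self.expand = Linear(dim, self.fd * 4 * (dim // 2), rng)
        self.norm = LayerNorm(dim // 2)

    def forward(self, x: Tensor) -> Tensor:
        c, d, h, w = x.shape
        fd = self.fd
        out_c = c // 2
        t = self.expand(_to_tokens(x))  # (D, H, W, fd*4*out_c)
        t = t.reshape(d, h, w, fd, 2, 2, out_c)
        t = t.transpose(0, 3, 1, 4, 2, 5, 6).reshape(d * fd, h * 2, w * 2, out_c)
        return _to_map(self.norm(t))


class FinalPatchExpand(Module):
    """Factor-``p`` expansion back to voxel resolution, keeping channels."""

    def __init__(self, dim: int, factor: int, rng):
        super().__init__()
        self.factor = factor
        self.expand = Linear(dim, factor**3 * dim, rng)
        self.norm = LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        c, d, h, w = x.shape
        p = self.factor
        t = self.expand(_to_tokens(x)).reshape(d, h, w, p, p, p, c)
        t = t.transpose(0, 3, 1, 4, 2, 5, 6).reshape(d * p, h * p, w * p, c)
        return _to_map(self.norm(t))


# ---------------------------------------------------------------------------
# transformer blocks


def _ln(x: Tensor, norm: LayerNorm) -> Tensor:
    return _to_map(norm(_to_tokens(x)))


class VTEncoderBlock(Module):
    """One W-MSA + SW-MSA sub-layer pair with pre-norm residuals.

    Returns the transformed map and the K/V pairs of both sub-layers for
    the encoder→decoder bridge.
    """

    def __init__(self, dim, heads, window, shift, rng, relative_bias, mlp_ratio):
        super().__init__()
        self.shift = tuple(shift)
        self.norm_a1 = LayerNorm(dim)
        self.attn_w = WindowAttention(dim, heads, window, rng, relative_bias)
        self.norm_a2 = LayerNorm(dim)
        self.mlp_a = Mlp(dim, int(dim * mlp_ratio), rng)
        self.norm_b1 = LayerNorm(dim)
        self.attn_sw = WindowAttention(dim, heads, window, rng, relative_bias)
        self.norm_b2 = LayerNorm(dim)
        self.mlp_b = Mlp(dim, int(dim * mlp_ratio), rng)

    def forward(self, x: Tensor) -> tuple[Tensor, AttentionKV]:
        out, k, v = wmsa(_ln(x, self.norm_a1), self.attn_w)
        x = x + out
        x = x + _to_map(self.mlp_a(self.norm_a2(_to_tokens(x))))
        out, ks, vs = swmsa(_ln(x, self.norm_b1), self.attn_sw, self.shift)
        x = x + out
        x = x + _to_map(self.mlp_b(self.norm_b2(_to_tokens(x))))
        return x, AttentionKV(k=k, v=v, k_shift=ks, v_shift=vs)


class VTDecoderBlock(Module):
    """Decoder pair: parallel self-/cross-attention merged by fusion.

    Each sub-layer projects queries from the decoder features, runs
    self-attention with its own K/V and cross-attention with the bridged
    encoder K/V (the shifted sub-layer uses the shifted cache and mask),
    and merges the branches with the convex-combination fusion block.
    """

    def __init__(self, dim, heads, window, shift, rng, relative_bias, mlp_ratio,
                 lam, fpe_freq):
        super().__init__()
        self.shift = tuple(shift)
        n_tokens = int(np.prod(window))
        self.norm_a = LayerNorm(dim)
        self.attn_w = WindowAttention(dim, heads, window, rng, relative_bias)
        self.fuse_a = FusionBlock(dim, n_tokens, rng, lam, fpe_freq, mlp_ratio)
        self.norm_b = LayerNorm(dim)
        self.attn_sw = WindowAttention(dim, heads, window, rng, relative_bias)
        self.fuse_b = FusionBlock(dim, n_tokens, rng, lam, fpe_freq, mlp_ratio)

    def _sublayer(self, x, norm, attn, fuse, shift, bk, bv):
        spatial = x.shape[1:]
        h = _ln(x, norm)
        shifted = cyclic_shift(h, tuple(-s for s in shift)) if any(shift) else h
        tokens = window_partition(shifted, attn.window_size)
        q, k, v = attn.project_qkv(tokens)
        if bk.shape != q.shape:
            raise ValidationError(
                f"bridged K/V shape {bk.shape} does not match stage queries {q.shape}"
            )
        mask = shift_attention_mask(spatial, attn.window_size, shift)
        sa = attn.attend(q, k, v, mask=mask)
        ca = attn.attend(q, bk, bv, mask=mask)
        fused = window_reverse(fuse(ca, sa), attn.window_size, spatial)
        if any(shift):
            fused = cyclic_shift(fused, shift)
        return x + fused

    def forward(self, x: Tensor, kv: AttentionKV) -> Tensor:
        x = self._sublayer(x, self.norm_a, self.attn_w, self.fuse_a,
                           (0, 0, 0), kv.k, kv.v)
        x = self._sublayer(x, self.norm_b, self.attn_sw, self.fuse_b,
                           self.shift, kv.k_shift, kv.v_shift)
        kv.consumed += 1
        return x


class _EncoderStage(Module):
    def __init__(self, blocks, gns, merge):
        super().__init__()
        self.blocks = blocks
        self.gns = gns
        self.merge = merge


class _DecoderStage(Module):
    def __init__(self, blocks, expand):
        super().__init__()
        self.blocks = blocks
        self.expand = expand  # None for the outermost stage


# ---------------------------------------------------------------------------
# the network


class GETNet(Module):
    """Full encoder / bottleneck / decoder assembly (see module docstring)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        common = (cfg.window_size, cfg.shift_size, rng, cfg.relative_bias,
                  cfg.mlp_ratio)

        self.patch_embed = PatchEmbed(cfg.in_channels, cfg.patch_size,
                                      cfg.embed_dim, rng)
        enc = []
        for i, depth in enumerate(cfg.depths):
            dim = cfg.stage_dim(i)
            blocks = ModuleList(
                VTEncoderBlock(dim, cfg.heads[i], *common) for _ in range(depth)
            )
            gns = GnsBlock(dim, rng, cfg.gns_layout, cfg.gn_groups)
            merge = PatchMerge(dim, cfg.depth_halving, rng)
            enc.append(_EncoderStage(blocks, gns, merge))
        self.encoder = ModuleList(enc)

        bott_dim = cfg.stage_dim(cfg.n_stages)
        self.bottleneck = ModuleList(
            EnhancedTransformer(bott_dim, rng, cfg.dwc_kernel, cfg.mlp_ratio)
            for _ in range(cfg.bottleneck_depth)
        )
        self.bottleneck_expand = PatchExpand(bott_dim, cfg.depth_halving, rng)

        dec = []
        for i in range(cfg.n_stages - 1, -1, -1):
            dim = cfg.stage_dim(i)
            blocks = ModuleList(
                VTDecoderBlock(dim, cfg.heads[i], *common, cfg.lam, cfg.fpe_freq)
                for _ in range(cfg.depths[i])
            )
            expand = PatchExpand(dim, cfg.depth_halving, rng) if i > 0 else None
            dec.append(_DecoderStage(blocks, expand))
        self.decoder = ModuleList(dec)

        self.final_expand = FinalPatchExpand(cfg.embed_dim, cfg.patch_size, rng)
        self.classifier = Conv1x1x1(cfg.embed_dim, cfg.out_channels, rng)
        self.last_kv_caches: list[list[AttentionKV]] = []

    def forward(self, vol) -> Tensor:
        """Map a (4, D, H, W) volume to (3, D, H, W) region logits."""
        x = vol if isinstance(vol, Tensor) else Tensor(np.asarray(vol))
        if x.ndim != 4 or x.shape[0] != self.cfg.in_channels:
            raise ValidationError(f"expected (4, D, H, W) input, got {x.shape}")
        self.cfg.stage_grids(x.shape[1:])  # raises before any compute

        x = self.patch_embed(x)
        caches: list[list[AttentionKV]] = []
        for stage in self.encoder:
            stage_kv = []
            for blk in stage.blocks:
                x, kv = blk(x)
                stage_kv.append(kv)
            caches.append(stage_kv)
            x = stage.merge(stage.gns(x))

        for block in self.bottleneck:
            x = block(x)
        x = self.bottleneck_expand(x)

        for rank, stage in enumerate(self.decoder):
            i = self.cfg.n_stages - 1 - rank
            stage_kv = caches[i]
            for j, blk in enumerate(stage.blocks):
                x = blk(x, stage_kv[len(stage_kv) - 1 - j])  # mirror order
            if stage.expand is not None:
                x = stage.expand(x)

        self.last_kv_caches = caches
        return self.classifier(self.final_expand(x))

    def predict_probs(self, vol) -> np.ndarray:
        """Per-region sigmoid probabilities, (3, D, H, W) numpy array."""
        return self.forward(vol).sigmoid().numpy()


def predict_labels(model: GETNet, vol, threshold: float = 0.5) -> SegmentationMask:
    """Threshold region probabilities and encode BraTS labels.

    Sigmoid → 0.5 threshold → hierarchy enforcement (via the region→label
    encoder) guarantees WT ⊇ TC ⊇ ET in the decoded output.
    """
    probs = model.predict_probs(vol)
    return regions_to_labels(RegionMask(probs >= threshold))


# ---------------------------------------------------------------------------
# analytic MAC counting


@dataclass
class MacCount:
    """Per-layer multiply–accumulate totals (1 MAC = one multiply-add;
    normalizations and activations are not counted)."""

    per_layer: dict[str, int] = field(default_factory=dict)

    def add(self, name: str, macs: int) -> None:
        self.per_layer[name] = self.per_layer.get(name, 0) + int(macs)

    @property
    def total(self) -> int:
        return sum(self.per_layer.values())


def count_macs(cfg: ModelConfig, input_shape: tuple[int, int, int]) -> MacCount:
    """Analytic MAC count of a full forward pass; nothing is executed."""
    cfg.validate()
    grids = cfg.stage_grids(input_shape)
    win_tokens = int(np.prod(cfg.window_size))
    mc = MacCount()

    def attention_layer(name, tokens, dim):
        # qkv + output projection + score and apply terms
        mc.add(name, tokens * dim * 3 * dim)
        mc.add(name, tokens * dim * dim)
        mc.add(name, 2 * tokens * win_tokens * dim)

    def mlp_layer(name, tokens, dim):
        hidden = int(dim * cfg.mlp_ratio)
        mc.add(name, 2 * tokens * dim * hidden)

    p = cfg.patch_size
    tokens0 = int(np.prod(grids[0]))
    mc.add("patch_embed", tokens0 * cfg.in_channels * p**3 * cfg.embed_dim)

    for i, depth in enumerate(cfg.depths):
        dim = cfg.stage_dim(i)
        tokens = int(np.prod(grids[i]))
        for _ in range(depth):
            for sub in ("w", "sw"):
                attention_layer(f"enc{i}_{sub}msa", tokens, dim)
                mlp_layer(f"enc{i}_mlp", tokens, dim)
        branch = dim // 2
        mc.add(f"gns{i}", tokens * branch * branch * 2)  # two 1×1×1 convs
        mc.add(f"gns{i}", tokens * branch * 27)  # 3³ depth-wise
        n_neigh = (2 if cfg.depth_halving else 1) * 4
        mc.add(f"merge{i}", int(np.prod(grids[i + 1])) * n_neigh * dim * 2 * dim)

    bott_dim = cfg.stage_dim(cfg.n_stages)
    bott_tokens = int(np.prod(grids[-1]))
    for _ in range(cfg.bottleneck_depth):
        # three FL maps + aggregation conv, gates, large-kernel DWC, MLP
        mc.add("bottleneck_ecsa", 4 * bott_tokens * bott_dim * bott_dim)
        mc.add("bottleneck_ecsa", 3 * 2 * bott_dim * bott_dim)
        mc.add("bottleneck_ecsa", bott_tokens * bott_dim * cfg.dwc_kernel**3)
        mlp_layer("bottleneck_mlp", bott_tokens, bott_dim)
    fd = 2 if cfg.depth_halving else 1
    mc.add("bottleneck_expand", bott_tokens * bott_dim * fd * 4 * (bott_dim // 2))

    for i in range(cfg.n_stages - 1, -1, -1):
        dim = cfg.stage_dim(i)
        tokens = int(np.prod(grids[i]))
        for _ in range(cfg.depths[i]):
            for sub in ("w", "sw"):
                attention_layer(f"dec{i}_{sub}msa_sa", tokens, dim)
                mc.add(f"dec{i}_{sub}msa_ca", 2 * tokens * win_tokens * dim)
                mc.add(f"dec{i}_{sub}msa_ca", tokens * dim * dim)  # shared proj
                mlp_layer(f"dec{i}_fusion_mlp", tokens, dim)
        if i > 0:
            mc.add(f"expand{i}", tokens * dim * fd * 4 * (dim // 2))

    mc.add("final_expand", tokens0 * cfg.embed_dim * p**3 * cfg.embed_dim)
    voxels = int(np.prod(input_shape))
    mc.add("classifier", voxels * cfg.embed_dim * cfg.out_channels)
    return mc


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: GETNet, path: str | Path) -> Path:
    """Save weights plus the embedded config as a compressed archive."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(asdict(model.cfg))
    np.savez_compressed(path, __config__=np.array(cfg_json), **model.state_dict())
    return path


def load_checkpoint(path: str | Path) -> GETNet:
    with np.load(path, allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["__config__"]))
        state = {k: data[k] for k in data.files if k != "__config__"}
    for key in ("depths", "heads", "window_size"):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg = ModelConfig(**cfg_dict)
    model = GETNet(cfg)
    model.load_state_dict(state)
    return model
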