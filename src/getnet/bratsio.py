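"""BraTS-style case I/O, preprocessing and label/region conversion.

A BraTS2021 case directory holds four co-registered modality volumes and
(for training cases) one label volume::

    BraTS2021_00000/
        BraTS2021_00000_t1.nii.gz
        BraTS2021_00000_t2.nii.gz
        BraTS2021_00000_t1ce.nii.gz
        BraTS2021_00000_flair.nii.gz
        BraTS2021_00000_seg.nii.gz     # optional

Labels use the BraTS alphabet {0, 1, 2, 4}: 1 necrotic/non-enhancing
core, 2 peritumoral edema, 4 enhancing tumor.  Evaluation happens on
three nested binary regions derived from the labels — whole tumor
WT = {1, 2, 4}, tumor core TC = {1, 4}, enhancing tumor ET = {4}.

Preprocessing follows the standard recipe: clip each channel to the 1st
and 99th percentiles of its nonzero-voxel distribution, standardize to
zero mean / unit variance over the nonzero voxels (background stays
exactly zero), then randomly crop a fixed-size patch that contains the
whole brain bounding box.  Augmentation offers random rotation (±30°),
additive Gaussian noise (sd 0.1), Gaussian blur (sigma 0.5–1) and a
gamma transform (exponent 0.7–1.5), each applied independently with a
configurable probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .synthdata import MODALITIES

__all__ = [
    "MultiModalVolume",
    "SegmentationMask",
    "RegionMask",
    "BRATS_LABELS",
    "REGION_NAMES",
    "read_case",
    "write_case",
    "clip_and_zscore",
    "crop_to_patch",
    "augment",
    "labels_to_regions",
    "regions_to_labels",
]

BRATS_LABELS = (0, 1, 2, 4)
REGION_NAMES = ("WT", "TC", "ET")

#: label subsets defining each evaluated region
_REGION_LABELS = {"WT": (1, 2, 4), "TC": (1, 4), "ET": (4,)}


@dataclass
class MultiModalVolume:
    """Four-channel intensity volume, channel order T1, T2, T1ce, FLAIR."""

    data: np.ndarray  # (4, D, H, W), float
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[0] != 4:
            raise ValidationError(
                f"expected (4, D, H, W) volume, got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume contains non-finite values")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass
class SegmentationMask:
    """Integer labels over the BraTS alphabet {0, 1, 2, 4}."""

    labels: np.ndarray  # (D, H, W), integer

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError(f"expected (D, H, W) mask, got {self.labels.shape}")
        bad = np.setdiff1d(np.unique(self.labels), BRATS_LABELS)
        if bad.size:
            raise ValidationError(f"unknown label values {bad.tolist()}")
        self.labels = self.labels.astype(np.uint8)


@dataclass
class RegionMask:
    """Binary nested region channels, order WT, TC, ET."""

    regions: np.ndarray  # (3, D, H, W), bool

    def __post_init__(self):
        self.regions = np.asarray(self.regions).astype(bool)
        if self.regions.ndim != 4 or self.regions.shape[0] != 3:
            raise ValidationError(
                f"expected (3, D, H, W) regions, got {self.regions.shape}"
            )


# ---------------------------------------------------------------------------
# NIfTI case I/O


def _modality_path(case_dir: Path, case_id: str, name: str) -> Path:
    return case_dir / f"{case_id}_{name}.nii.gz"


def write_case(
    volume: np.ndarray,
    labels: np.ndarray | None,
    case_dir: str | Path,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> Path:
    """Write a (4, D, H, W) volume (and optional labels) as a BraTS case dir."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    case_id = case_dir.name
    affine = np.diag(list(spacing) + [1.0])
    for ch, name in enumerate(MODALITIES):
        img = nib.Nifti1Image(np.asarray(volume[ch], dtype=np.float64), affine)
        nib.save(img, _modality_path(case_dir, case_id, name))
    if labels is not None:
        img = nib.Nifti1Image(np.asarray(labels, dtype=np.uint8), affine)
        nib.save(img, _modality_path(case_dir, case_id, "seg"))
    return case_dir


def read_case(case_dir: str | Path) -> tuple[MultiModalVolume, SegmentationMask | None]:
    """Load one case directory; the label volume is optional.

    Volumes are reoriented to the closest RAS-canonical axes so that all
    downstream code sees one fixed axis convention regardless of the
    affine stored on disk.
    """
    case_dir = Path(case_dir)
    case_id = case_dir.name
    channels = []
    spacing = None
    for name in MODALITIES:
        path = _modality_path(case_dir, case_id, name)
        if not path.exists():
            raise FileNotFoundError(f"missing modality file: {path}")
        img = nib.as_closest_canonical(nib.load(path))
        channels.append(np.asarray(img.get_fdata(), dtype=np.float64))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        if spacing is None:
            spacing = zooms
    shapes = {c.shape for c in channels}
    if len(shapes) != 1:
        raise ValidationError(f"modalities disagree on grid shape: {sorted(shapes)}")
    volume = MultiModalVolume(np.stack(channels), spacing)

    seg_path = _modality_path(case_dir, case_id, "seg")
    mask = None
    if seg_path.exists():
        img = nib.as_closest_canonical(nib.load(seg_path))
        lab = np.rint(img.get_fdata()).astype(np.int64)
        if lab.shape != volume.spatial_shape:
            raise ValidationError(
                f"label grid {lab.shape} does not match volume {volume.spatial_shape}"
            )
        mask = SegmentationMask(lab)
    return volume, mask


# ---------------------------------------------------------------------------
# Preprocessing


def clip_and_zscore(vol: MultiModalVolume) -> MultiModalVolume:
    """Percentile-clip and standardize each channel over its nonzero voxels.

    Per channel: intensities are clipped to the 1st/99th percentile of
    the nonzero-voxel distribution (linear-interpolation percentiles),
    then shifted/scaled so the nonzero voxels have zero mean and unit
    (population) variance.  Background zeros are left exactly zero.
    """
    out = np.zeros_like(vol.data)
    for ch in range(4):
        img = vol.data[ch]
        nz = img != 0
        if not nz.any():
            raise ValidationError(f"channel {ch} is all-zero; cannot standardize")
        values = img[nz]
        lo, hi = np.percentile(values, [1.0, 99.0])
        clipped = np.clip(values, lo, hi)
        mu = clipped.mean()
        sd = clipped.std()
        if sd == 0:
            raise ValidationError(f"channel {ch} has zero variance after clipping")
        out[ch, nz] = (clipped - mu) / sd
    return MultiModalVolume(out, vol.spacing)


def _brain_bbox(data: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive bounding box of the union of nonzero voxels across channels."""
    union = np.any(data != 0, axis=0)
    if not union.any():
        return [(0, s - 1) for s in data.shape[1:]]
    bbox = []
    for ax in range(3):
        other = tuple(a for a in range(3) if a != ax)
        prof = union.any(axis=other)
        idx = np.flatnonzero(prof)
        bbox.append((int(idx[0]), int(idx[-1])))
    return bbox


def crop_to_patch(
    vol: MultiModalVolume,
    mask: SegmentationMask | None,
    size: tuple[int, int, int] = (128, 128, 128),
    rng: int | np.random.Generator = 0,
) -> tuple[MultiModalVolume, SegmentationMask | None]:
    """Randomly crop a fixed-size patch containing the brain bounding box.

    The crop window is drawn uniformly among all windows that contain the
    brain bounding box along each axis; inputs smaller than the patch are
    zero-padded first, which preserves brain voxels.  If the bounding box
    exceeds the patch along an axis the window is drawn among positions
    maximizing overlap.  Identical seeds yield identical windows.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    data = vol.data
    lab = mask.labels if mask is not None else None

    pad_spec = [(0, 0)]
    for ax, s in enumerate(size):
        short = max(0, s - data.shape[1 + ax])
        pad_spec.append((short // 2, short - short // 2))
    if any(p != (0, 0) for p in pad_spec):
        data = np.pad(data, pad_spec)
        if lab is not None:
            lab = np.pad(lab, pad_spec[1:])

    bbox = _brain_bbox(data)
    starts = []
    for ax, s in enumerate(size):
        lo, hi = bbox[ax]
        dim = data.shape[1 + ax]
        a = max(0, hi + 1 - s)
        b = min(dim - s, lo)
        if a > b:  # bounding box larger than the patch: maximize overlap
            a, b = b, a
        starts.append(int(rng.integers(a, b + 1)))
    sl = tuple(slice(st, st + s) for st, s in zip(starts, size))
    out_vol = MultiModalVolume(data[(slice(None),) + sl], vol.spacing)
    out_mask = SegmentationMask(lab[sl]) if lab is not None else None
    return out_vol, out_mask


# ---------------------------------------------------------------------------
# Augmentation

_ROTATION_PLANES = ((0, 1), (0, 2), (1, 2))  # spatial axis pairs


def augment(
    vol: MultiModalVolume,
    mask: SegmentationMask | None,
    rng: int | np.random.Generator = 0,
    p_apply: float = 0.5,
) -> tuple[MultiModalVolume, SegmentationMask | None]:
    """Stochastic augmentation: rotation, noise, blur, gamma.

    Each transform fires independently with probability ``p_apply``:

    * rotation by an angle ~ U(−30°, 30°) in a random orthogonal plane,
      linear interpolation for intensities, nearest-neighbour for labels;
    * additive Gaussian noise, sd 0.1;
    * Gaussian blur, sigma ~ U(0.5, 1) (spatial axes only);
    * gamma transform, exponent ~ U(0.7, 1.5), applied to intensities
      rescaled to [0, 1] per channel so negative (standardized) values
      are handled.

    The label volume is only ever transformed geometrically.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    data = vol.data.copy()
    lab = mask.labels.copy() if mask is not None else None

    if rng.random() < p_apply:  # rotation
        angle = rng.uniform(-30.0, 30.0)
        plane = _ROTATION_PLANES[rng.integers(0, 3)]
        vol_axes = (plane[0] + 1, plane[1] + 1)  # offset past channel axis
        data = ndimage.rotate(
            data, angle, axes=vol_axes, reshape=False, order=1, mode="constant"
        )
        if lab is not None:
            lab = ndimage.rotate(
                lab, angle, axes=plane, reshape=False, order=0, mode="constant"
            )
    if rng.random() < p_apply:  # additive Gaussian noise
        data = data + rng.normal(0.0, 0.1, size=data.shape)
    if rng.random() < p_apply:  # Gaussian blur
        sigma = rng.uniform(0.5, 1.0)
        data = ndimage.gaussian_filter(data, sigma=(0.0, sigma, sigma, sigma))
    if rng.random() < p_apply:  # gamma transform on [0, 1]-rescaled intensities
        gamma = rng.uniform(0.7, 1.5)
        for ch in range(4):
            img = data[ch]
            lo, hi = img.min(), img.max()
            if hi > lo:
                data[ch] = ((img - lo) / (hi - lo)) ** gamma * (hi - lo) + lo

    out_mask = SegmentationMask(lab) if lab is not None else None
    return MultiModalVolume(data, vol.spacing), out_mask


# ---------------------------------------------------------------------------
# Label/region conversion


def labels_to_regions(mask: SegmentationMask) -> RegionMask:
    """Decode BraTS labels into the nested WT/TC/ET binary channels."""
    lab = mask.labels
    regions = np.stack(
        [np.isin(lab, _REGION_LABELS[name]) for name in REGION_NAMES]
    )
    return RegionMask(regions)


def regions_to_labels(regions: RegionMask) -> SegmentationMask:
    """Encode WT/TC/ET channels back to BraTS labels.

    The region hierarchy is enforced first (TC := TC ∧ WT, ET := ET ∧ TC),
    so stray positives outside their parent region are suppressed; the
    composition with :func:`labels_to_regions` is then the identity on
    hierarchy-consistent inputs.
    """
    wt, tc, et = regions.regions
    tc = tc & wt
    et = et & tc
    lab = np.zeros(wt.shape, dtype=np.uint8)
    lab[wt & ~tc] = 2
    lab[tc & ~et] = 1
    lab[et] = 4
    return SegmentationMask(lab)
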