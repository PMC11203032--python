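"""Deterministic multi-modal MRI phantoms with nested tumor regions.

Real BraTS cases are four co-registered modalities (T1, T2, T1ce, FLAIR)
over a skull-stripped brain, with expert labels that decode into three
nested evaluation regions: whole tumor ⊇ tumor core ⊇ enhancing tumor.
The phantoms emulate exactly that structure — a brain ellipsoid of
nonzero intensity on an exactly-zero background, three nested
axis-aligned lesion ellipsoids, piecewise-constant tissue means with
modality-dependent contrast (edema brightest on the FLAIR-like channel,
the enhancing rim brightest on the T1ce-like channel) plus Gaussian
noise.  They carry none of the physics of real MRI (no bias field, no
partial-volume effect, no anatomy), but they exercise every contract the
rest of the package relies on: nonzero-voxel normalization, label
decoding, cropping, and end-to-end training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ValidationError

__all__ = ["PhantomSpec", "generate_phantom", "MODALITIES", "TISSUE_MEANS"]

MODALITIES = ("t1", "t2", "t1ce", "flair")

#: Mean intensity per (modality, tissue).  Tissue keys: healthy brain,
#: edema (label 2), necrotic/non-enhancing core (label 1), enhancing (label 4).
TISSUE_MEANS = {
    "t1": {"brain": 1.0, 2: 0.7, 1: 0.4, 4: 0.9},
    "t2": {"brain": 0.8, 2: 1.3, 1: 1.1, 4: 1.0},
    "t1ce": {"brain": 1.0, 2: 0.8, 1: 0.3, 4: 1.8},
    "flair": {"brain": 0.9, 2: 1.7, 1: 1.0, 4: 1.2},
}

#: Brain ellipsoid semi-axis as a fraction of each grid dimension.
_BRAIN_FRACTION = 0.45


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast noise and seed of one synthetic case.

    ``region_radii`` are the semi-axes of the WT, TC and ET ellipsoids,
    in voxels, and must be strictly decreasing along every axis (an ET
    radius of 0 is allowed and yields an empty enhancing region).
    ``divisible_by`` guards the spatial shape against the segmentation
    model's total downsampling factor.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    lesion_center: tuple[float, float, float] = (16.0, 16.0, 16.0)
    region_radii: tuple[tuple[float, ...], ...] = (
        (10.0, 10.0, 10.0),
        (6.0, 6.0, 6.0),
        (3.0, 3.0, 3.0),
    )
    noise_sd: float = 0.05
    seed: int = 0
    divisible_by: int = 16
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def validate(self) -> None:
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ConfigurationError(f"invalid shape {self.shape}")
        if any(s % self.divisible_by != 0 for s in self.shape):
            raise ConfigurationError(
                f"shape {self.shape} not divisible by {self.divisible_by}"
            )
        if len(self.region_radii) != 3:
            raise ValidationError("region_radii must hold WT, TC, ET triples")
        wt, tc, et = (np.asarray(r, dtype=float) for r in self.region_radii)
        for outer, inner, names in ((wt, tc, "WT>TC"), (tc, et, "TC>ET")):
            # inner may be all-zero (empty region); otherwise strict nesting
            if np.any(inner > 0) and not np.all(outer > inner):
                raise ValidationError(f"region radii not strictly nested ({names})")
            if np.all(inner == 0):
                continue
        if np.any(wt <= 0):
            raise ValidationError("WT radii must be positive")
        # lesion must sit fully inside the brain ellipsoid (conservative,
        # per-axis check)
        centre = np.asarray(self.lesion_center, dtype=float)
        grid_centre = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        brain_semi = _BRAIN_FRACTION * np.asarray(self.shape, dtype=float)
        if np.any(np.abs(centre - grid_centre) + wt > brain_semi):
            raise ValidationError("lesion extends outside the brain ellipsoid")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")


def _ellipsoid_mask(shape, centre, semi_axes) -> np.ndarray:
    semi = np.asarray(semi_axes, dtype=float)
    if np.all(semi <= 0):
        return np.zeros(shape, dtype=bool)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, centre, semi):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one phantom case.

    Returns ``(volume, labels)`` with ``volume`` of shape ``(4, D, H, W)``
    (channel order T1, T2, T1ce, FLAIR) and ``labels`` of shape
    ``(D, H, W)`` over the BraTS alphabet {0, 1, 2, 4}.  The same spec
    (including its seed) always produces bit-identical arrays.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    grid_centre = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    brain = _ellipsoid_mask(shape, grid_centre, _BRAIN_FRACTION * np.asarray(shape))

    wt, tc, et = (
        _ellipsoid_mask(shape, spec.lesion_center, r) for r in spec.region_radii
    )
    tc &= wt
    et &= tc

    labels = np.zeros(shape, dtype=np.uint8)
    labels[wt] = 2  # peritumoral edema
    labels[tc] = 1  # necrotic / non-enhancing core
    labels[et] = 4  # enhancing tumor

    volume = np.zeros((4,) + shape, dtype=np.float64)
    for ch, modality in enumerate(MODALITIES):
        means = TISSUE_MEANS[modality]
        img = np.zeros(shape, dtype=np.float64)
        img[brain] = means["brain"]
        for lab in (2, 1, 4):
            img[labels == lab] = means[lab]
        noise = rng.normal(0.0, spec.noise_sd, size=shape)
        img[brain] += noise[brain]
        # keep brain intensities strictly positive so the zero background
        # stays the only zero-valued structure
        img[brain] = np.clip(img[brain], 1e-3, None)
        volume[ch] = img
    return volume, labels
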