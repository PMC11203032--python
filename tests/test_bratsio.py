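"""Case I/O, preprocessing, augmentation and label/region conversion."""

import itertools

import numpy as np
import pytest

from getnet.bratsio import (
    MultiModalVolume,
    RegionMask,
    SegmentationMask,
    augment,
    clip_and_zscore,
    crop_to_patch,
    labels_to_regions,
    read_case,
    regions_to_labels,
    write_case,
)
from getnet.errors import ValidationError


# ---------------------------------------------------------------------------
# NIfTI round trips


def test_write_read_round_trip_is_bit_identical(phantom, tmp_path):
    vol, lab = phantom
    case = write_case(vol, lab, tmp_path / "CASE_000")
    loaded_vol, loaded_mask = read_case(case)
    np.testing.assert_array_equal(loaded_vol.data, vol)
    np.testing.assert_array_equal(loaded_mask.labels, lab)
    assert loaded_vol.spacing == (1.0, 1.0, 1.0)


def test_case_without_seg_loads_volume_with_absent_mask(phantom, tmp_path):
    vol, _ = phantom
    case = write_case(vol, None, tmp_path / "CASE_001")
    loaded_vol, mask = read_case(case)
    assert mask is None
    assert loaded_vol.data.shape == vol.shape


def test_missing_modality_raises_naming_the_file(phantom, tmp_path):
    vol, lab = phantom
    case = write_case(vol, lab, tmp_path / "CASE_002")
    missing = case / "CASE_002_t1ce.nii.gz"
    missing.unlink()
    with pytest.raises(FileNotFoundError, match="t1ce"):
        read_case(case)


def test_mismatched_grid_raises(phantom, tmp_path):
    import nibabel as nib

    vol, lab = phantom
    case = write_case(vol, lab, tmp_path / "CASE_003")
    small = nib.Nifti1Image(np.zeros((16, 16, 16)), np.eye(4))
    nib.save(small, case / "CASE_003_t2.nii.gz")
    with pytest.raises(ValidationError):
        read_case(case)


# ---------------------------------------------------------------------------
# clip + Z-score


def test_zscore_nonzero_voxels_standardized_background_zero(phantom_case):
    vol, _ = phantom_case
    out = clip_and_zscore(vol)
    for ch in range(4):
        nz_in = vol.data[ch] != 0
        values = out.data[ch][nz_in]
        assert abs(values.mean()) < 1e-6
        assert abs(values.var() - 1.0) < 1e-6
        assert (out.data[ch][~nz_in] == 0.0).all()


def test_extreme_outlier_is_clipped_to_99th_percentile(phantom_case):
    vol, _ = phantom_case
    data = vol.data.copy()
    nz = data[0] != 0
    idx = tuple(np.argwhere(nz)[0])
    data[0][idx] = 1e6
    hi = np.percentile(data[0][data[0] != 0], 99.0)
    out = clip_and_zscore(MultiModalVolume(data))
    values = data[0][data[0] != 0]
    clipped = np.clip(values, np.percentile(values, 1.0), hi)
    expected = (clipped - clipped.mean()) / clipped.std()
    np.testing.assert_allclose(np.sort(out.data[0][data[0] != 0]),
                               np.sort(expected), atol=1e-9)
    # the outlier landed exactly at the upper clip bound
    assert out.data[0][idx] == pytest.approx(expected.max())


def test_zscore_is_idempotent_up_to_tolerance():
    """Without noise tails there is nothing for the percentile clip to cut,
    and re-standardizing standardized data is a no-op."""
    from getnet.synthdata import PhantomSpec, generate_phantom

    vol = MultiModalVolume(generate_phantom(PhantomSpec(noise_sd=0.0))[0])
    once = clip_and_zscore(vol)
    twice = clip_and_zscore(once)
    np.testing.assert_allclose(twice.data, once.data, atol=1e-5)


def test_all_zero_channel_rejected():
    data = np.zeros((4, 8, 8, 8))
    data[1:, 2:6, 2:6, 2:6] = 1.0
    with pytest.raises(ValidationError):
        clip_and_zscore(MultiModalVolume(data))


# ---------------------------------------------------------------------------
# cropping


def test_crop_is_deterministic_and_contains_brain(phantom_case):
    vol, mask = phantom_case
    a = crop_to_patch(vol, mask, (16, 16, 16), rng=7)
    b = crop_to_patch(vol, mask, (16, 16, 16), rng=7)
    np.testing.assert_array_equal(a[0].data, b[0].data)
    np.testing.assert_array_equal(a[1].labels, b[1].labels)
    assert a[0].data.shape == (4, 16, 16, 16)


def test_small_input_zero_padded_preserving_brain(phantom_case):
    vol, mask = phantom_case
    out_vol, out_mask = crop_to_patch(vol, mask, (48, 48, 48), rng=0)
    assert out_vol.data.shape == (4, 48, 48, 48)
    assert (out_vol.data != 0).sum() == (vol.data != 0).sum()
    assert out_mask.labels.sum() == mask.labels.sum()


def test_exact_fit_window_is_uniquely_determined():
    data = np.zeros((4, 16, 16, 16))
    data[:, :, :, :] = 1.0  # brain fills the grid: only one feasible window
    vol = MultiModalVolume(data)
    for seed in range(5):
        out, _ = crop_to_patch(vol, None, (16, 16, 16), rng=seed)
        np.testing.assert_array_equal(out.data, data)


# ---------------------------------------------------------------------------
# augmentation


def test_p_zero_is_identity(phantom_case):
    vol, mask = phantom_case
    out_vol, out_mask = augment(vol, mask, rng=3, p_apply=0.0)
    np.testing.assert_array_equal(out_vol.data, vol.data)
    np.testing.assert_array_equal(out_mask.labels, mask.labels)


def test_augment_deterministic_and_preserves_label_alphabet(phantom_case):
    vol, mask = phantom_case
    a = augment(vol, mask, rng=11, p_apply=1.0)
    b = augment(vol, mask, rng=11, p_apply=1.0)
    np.testing.assert_array_equal(a[0].data, b[0].data)
    np.testing.assert_array_equal(a[1].labels, b[1].labels)
    assert set(np.unique(a[1].labels)) <= {0, 1, 2, 4}


def test_rotation_round_trip_approximately_preserves_label_counts(phantom_case):
    from scipy import ndimage

    _, mask = phantom_case
    angle = 17.0
    rot = ndimage.rotate(mask.labels, angle, axes=(0, 1), reshape=False, order=0)
    back = ndimage.rotate(rot, -angle, axes=(0, 1), reshape=False, order=0)
    for lab in (1, 2, 4):
        n0 = (mask.labels == lab).sum()
        n1 = (back == lab).sum()
        assert abs(n1 - n0) <= 0.15 * n0 + 10


def test_gamma_exponent_one_is_intensity_identity(phantom_case):
    vol, _ = phantom_case
    img = vol.data[0]
    lo, hi = img.min(), img.max()
    out = ((img - lo) / (hi - lo)) ** 1.0 * (hi - lo) + lo
    np.testing.assert_allclose(out, img, atol=1e-12)


# ---------------------------------------------------------------------------
# label/region conversion


def test_single_label_decodings():
    lab = np.zeros((1, 1, 1), dtype=np.uint8)
    for value, expected in [(4, (1, 1, 1)), (2, (1, 0, 0)), (1, (1, 1, 0)),
                            (0, (0, 0, 0))]:
        lab[0, 0, 0] = value
        regions = labels_to_regions(SegmentationMask(lab)).regions
        assert tuple(int(r[0, 0, 0]) for r in regions) == expected


def test_unknown_label_rejected():
    with pytest.raises(ValidationError):
        SegmentationMask(np.full((2, 2, 2), 3))


@pytest.mark.parametrize("bits", list(itertools.product([0, 1], repeat=3)))
def test_region_label_round_trip_on_all_bit_patterns(bits):
    """Hierarchy-consistent patterns round-trip exactly; inconsistent ones
    are suppressed to their consistent core by hierarchy enforcement."""
    wt, tc, et = bits
    regions = RegionMask(np.array(bits, dtype=bool).reshape(3, 1, 1, 1))
    lab = regions_to_labels(regions)
    back = labels_to_regions(lab).regions
    # the enforced-consistent version of the input
    tc_c = tc and wt
    et_c = et and tc_c
    assert tuple(int(b[0, 0, 0]) for b in back) == (wt, tc_c, et_c)


def test_region_round_trip_on_phantom(phantom_case):
    _, mask = phantom_case
    back = regions_to_labels(labels_to_regions(mask))
    np.testing.assert_array_equal(back.labels, mask.labels)
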