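"""Metric definitions against brute-force tallies and closed-form cases."""

import numpy as np
import pytest

from getnet.bratsio import SegmentationMask
from getnet.errors import ValidationError
from getnet.metrics import (
    ConfusionCounts,
    confusion,
    dice,
    evaluate_case,
    hd95,
    reports_to_dataframe,
    sensitivity,
    soft_dice_loss,
    specificity,
)
from oracles import hd95_oracle


def test_confusion_matches_exhaustive_voxel_tally(rng):
    pred = rng.random((3, 3, 3)) > 0.5
    truth = rng.random((3, 3, 3)) > 0.5
    c = confusion(pred, truth)
    tp = fp = fn = tn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
    assert c.total == 27


def test_confusion_simple_cases():
    ones = np.ones((2, 2, 2), dtype=bool)
    zeros = np.zeros((2, 2, 2), dtype=bool)
    assert confusion(ones, ones) == ConfusionCounts(8, 0, 0, 0)
    assert confusion(ones, zeros) == ConfusionCounts(0, 8, 0, 0)
    with pytest.raises(ValidationError):
        confusion(ones, np.ones((2, 2, 3), dtype=bool))


@pytest.mark.parametrize(
    "counts, expected",
    [
        (ConfusionCounts(5, 0, 0, 3), 1.0),
        (ConfusionCounts(0, 2, 1, 5), 0.0),
        (ConfusionCounts(2, 1, 1, 4), 4.0 / 6.0),
        (ConfusionCounts(0, 0, 0, 8), 1.0),  # empty-empty convention
    ],
)
def test_dice_values(counts, expected):
    assert dice(counts) == pytest.approx(expected)


def test_sensitivity_specificity_values():
    assert sensitivity(ConfusionCounts(3, 0, 1, 0)) == pytest.approx(0.75)
    assert sensitivity(ConfusionCounts(2, 5, 0, 1)) == 1.0
    assert specificity(ConfusionCounts(0, 0, 2, 6)) == 1.0
    assert np.isnan(sensitivity(ConfusionCounts(0, 3, 0, 5)))
    assert np.isnan(specificity(ConfusionCounts(4, 0, 4, 0)))


def test_metrics_on_all_2cubed_mask_pairs():
    """Dice / sensitivity / specificity agree with direct count formulas on
    every pair of 2³ binary masks (65,536 pairs)."""
    patterns = [
        np.array([(i >> b) & 1 for b in range(8)], dtype=bool).reshape(2, 2, 2)
        for i in range(256)
    ]
    for i, pred in enumerate(patterns):
        for truth in patterns:
            c = confusion(pred, truth)
            tp = int((pred & truth).sum())
            fp = int((pred & ~truth).sum())
            fn = int((~pred & truth).sum())
            tn = 8 - tp - fp - fn
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
            d = dice(c)
            if 2 * tp + fp + fn:
                assert d == 2 * tp / (2 * tp + fp + fn)
            else:
                assert d == 1.0
            if tp + fn:
                assert sensitivity(c) == tp / (tp + fn)
            if tn + fp:
                assert specificity(c) == tn / (tn + fp)


# ---------------------------------------------------------------------------
# HD95


def test_hd95_identical_masks_is_zero(phantom_case):
    _, mask = phantom_case
    wt = mask.labels > 0
    assert hd95(wt, wt) == 0.0


def test_hd95_singletons_three_apart():
    a = np.zeros((8, 8, 8), dtype=bool)
    b = np.zeros((8, 8, 8), dtype=bool)
    a[2, 4, 4] = True
    b[5, 4, 4] = True
    assert hd95(a, b) == pytest.approx(3.0)


def test_hd95_empty_mask_gives_nan_sentinel():
    a = np.zeros((4, 4, 4), dtype=bool)
    b = np.zeros((4, 4, 4), dtype=bool)
    b[1, 1, 1] = True
    assert np.isnan(hd95(a, b))
    assert np.isnan(hd95(b, a))
    assert np.isnan(hd95(a, a))


@pytest.mark.parametrize("seed", range(10))
def test_hd95_matches_all_pairs_oracle(seed):
    rng = np.random.default_rng(seed)
    a = rng.random((5, 5, 5)) > 0.6
    b = rng.random((5, 5, 5)) > 0.6
    if not a.any() or not b.any():
        pytest.skip("degenerate draw")
    assert hd95(a, b) == pytest.approx(hd95_oracle(a, b), abs=1e-9)


def test_hd95_symmetry_translation_and_spacing(rng):
    a = rng.random((6, 6, 6)) > 0.5
    b = rng.random((6, 6, 6)) > 0.5
    assert hd95(a, b) == pytest.approx(hd95(b, a))
    # translating both masks together leaves the distance unchanged
    big_a, big_b = np.zeros((9, 9, 9), bool), np.zeros((9, 9, 9), bool)
    big_a[:6, :6, :6], big_b[:6, :6, :6] = a, b
    moved_a, moved_b = np.zeros((9, 9, 9), bool), np.zeros((9, 9, 9), bool)
    moved_a[2:8, 2:8, 2:8], moved_b[2:8, 2:8, 2:8] = a, b
    assert hd95(moved_a, moved_b) == pytest.approx(hd95(big_a, big_b))
    assert hd95(a, b, spacing=(2.0, 2.0, 2.0)) == pytest.approx(2.0 * hd95(a, b))


# ---------------------------------------------------------------------------
# soft Dice loss


def test_soft_dice_loss_extremes(rng):
    t = (rng.random((3, 4, 4, 4)) > 0.5).astype(float)
    assert soft_dice_loss(t, t) == pytest.approx(0.0, abs=1e-4)
    assert soft_dice_loss(1.0 - t, t) == pytest.approx(1.0, abs=1e-4)


def test_soft_dice_loss_hand_computed_value():
    """Uniform 0.5 probabilities against a half-filled 2³ target."""
    t = np.zeros((3, 2, 2, 2))
    t[:, :1] = 1.0  # 4 positive voxels per region
    p = np.full((3, 2, 2, 2), 0.5)
    eps = 1e-5
    expected = 1.0 - (2 * (0.5 * 4) + eps) / (0.5 * 8 + 4 + eps)
    assert soft_dice_loss(p, t) == pytest.approx(expected, abs=1e-12)


def test_soft_dice_loss_shape_mismatch_rejected():
    with pytest.raises(ValidationError):
        soft_dice_loss(np.zeros((3, 2, 2, 2)), np.zeros((3, 2, 2, 4)))


# ---------------------------------------------------------------------------
# per-case evaluation


def test_evaluate_case_perfect_prediction(phantom_case):
    _, mask = phantom_case
    report = evaluate_case(mask, mask)
    for name in ("WT", "TC", "ET"):
        m = report.regions[name]
        assert m.dice == 1.0
        assert m.hd95 == 0.0
        assert m.sensitivity == 1.0
        assert m.specificity == 1.0


def test_evaluate_case_empty_et_conventions():
    lab = np.zeros((4, 4, 4), dtype=np.uint8)
    lab[1:3, 1:3, 1:3] = 2  # edema only: WT nonempty, TC/ET empty
    report = evaluate_case(SegmentationMask(lab), SegmentationMask(lab))
    assert report.regions["ET"].dice == 1.0
    assert np.isnan(report.regions["ET"].hd95)
    assert np.isnan(report.regions["ET"].sensitivity)


def test_cohort_mean_matches_hand_average(phantom_case):
    _, mask = phantom_case
    r = evaluate_case(mask, mask)
    df = reports_to_dataframe({"a": r, "b": r})
    assert df.loc["mean", "dice_WT"] == pytest.approx(1.0)
    assert df.shape[0] == 3
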