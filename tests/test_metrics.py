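"""Metric suite against brute-force confusion-count oracles."""

import numpy as np
import pytest
from skimage import draw

from leafseg import (dice, evaluate_masks, iou, lesion_geometry_rmse,
                     pixel_accuracy, precision_recall_f1)


def _brute_counts(pred, gt, cid):
    tp = fp = fn = 0
    for p, g in zip(pred.ravel(), gt.ravel()):
        if p == cid and g == cid:
            tp += 1
        elif p == cid:
            fp += 1
        elif g == cid:
            fn += 1
    return tp, fp, fn


def test_identity_masks_score_perfectly():
    m = np.array([[0, 1, 1], [2, 2, 0], [0, 1, 2]])
    assert dice(m, m, 2) == 1.0
    assert iou(m, m, 1) == 1.0
    assert pixel_accuracy(m, m) == 1.0
    assert precision_recall_f1(m, m, 2) == (1.0, 1.0, 1.0)


def test_disjoint_masks_score_zero():
    a = np.array([[1, 1], [0, 0]])
    b = np.array([[0, 0], [1, 1]])
    assert dice(a, b, 1) == 0.0
    assert iou(a, b, 1) == 0.0


def test_counting_oracles_on_toy_grids():
    # |P|=4, |G|=4, overlap 2 -> dice 0.5
    p = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 0]])
    g = np.array([[0, 1, 1], [0, 1, 1], [0, 0, 0]])
    assert dice(p, g, 1) == pytest.approx(0.5)
    # |P∩G|=2, |P∪G|=6 -> IoU 1/3
    assert iou(p, g, 1) == pytest.approx(2 / 6)
    # 3x3 grid with 7 matching pixels
    p2 = np.array([[0, 0, 1], [1, 1, 0], [0, 0, 0]])
    g2 = np.array([[0, 0, 1], [1, 1, 0], [0, 1, 1]])
    assert pixel_accuracy(p2, g2) == pytest.approx(7 / 9)
    # TP=2, FP=1, FN=2
    p3 = np.array([1, 1, 1, 0, 0])
    g3 = np.array([1, 1, 0, 1, 1])
    pr, rc, f1 = precision_recall_f1(p3, g3, 1)
    assert (pr, rc, f1) == (pytest.approx(2 / 3), pytest.approx(0.5),
                            pytest.approx(4 / 7))


def test_empty_empty_convention_and_zero_denominator(caplog):
    z = np.zeros((3, 3), dtype=int)
    assert dice(z, z, 1) == 1.0
    assert iou(z, z, 1) == 1.0
    gt = np.array([[1, 0], [0, 0]])
    pr, rc, f1 = precision_recall_f1(np.zeros_like(gt), gt, 1)
    assert (pr, rc, f1) == (0.0, 0.0, 0.0)


def test_metrics_match_brute_force_oracle(rand_mask_pairs):
    for pred, gt in rand_mask_pairs:
        for cid in range(int(max(pred.max(), gt.max())) + 1):
            tp, fp, fn = _brute_counts(pred, gt, cid)
            d_exp = 1.0 if 2 * tp + fp + fn == 0 else 2 * tp / (2 * tp + fp + fn)
            j_exp = 1.0 if tp + fp + fn == 0 else tp / (tp + fp + fn)
            assert abs(dice(pred, gt, cid) - d_exp) < 1e-12
            assert abs(iou(pred, gt, cid) - j_exp) < 1e-12
        assert abs(pixel_accuracy(pred, gt) - np.mean(pred == gt)) < 1e-12


def test_dice_iou_algebraic_identity(rand_mask_pairs):
    for pred, gt in rand_mask_pairs:
        for cid in range(int(max(pred.max(), gt.max())) + 1):
            j = iou(pred, gt, cid)
            assert abs(dice(pred, gt, cid) - 2 * j / (1 + j)) < 1e-12


def test_f1_is_harmonic_mean(rand_mask_pairs):
    for pred, gt in rand_mask_pairs[:50]:
        pr, rc, f1 = precision_recall_f1(pred, gt, 1)
        if pr + rc > 0:
            assert f1 == pytest.approx(2 * pr * rc / (pr + rc), abs=1e-12)


def test_evaluate_masks_micro_matches_pooled_counts(rng):
    preds = [rng.integers(0, 3, size=(8, 8)) for _ in range(5)]
    gts = [rng.integers(0, 3, size=(8, 8)) for _ in range(5)]
    rep = evaluate_masks(preds, gts, [0, 1, 2])
    tp = fp = fn = 0
    for p, g in zip(preds, gts):
        for cid in (0, 1, 2):
            t, f_, n_ = _brute_counts(p, g, cid)
            tp, fp, fn = tp + t, fp + f_, fn + n_
    assert rep.micro["iou"] == pytest.approx(tp / (tp + fp + fn), abs=1e-12)
    assert rep.micro["dice"] == pytest.approx(2 * tp / (2 * tp + fp + fn), abs=1e-12)
    assert rep.micro["precision"] == pytest.approx(tp / (tp + fp), abs=1e-12)


def test_evaluate_masks_is_permutation_invariant(rng):
    preds = [rng.integers(0, 3, size=(6, 6)) for _ in range(6)]
    gts = [rng.integers(0, 3, size=(6, 6)) for _ in range(6)]
    rep1 = evaluate_masks(preds, gts, [0, 1, 2])
    order = rng.permutation(6)
    rep2 = evaluate_masks([preds[i] for i in order], [gts[i] for i in order], [0, 1, 2])
    assert rep1.micro == rep2.micro
    assert rep1.per_class == rep2.per_class


def test_evaluate_masks_perfect_prediction():
    gts = [np.array([[0, 1], [2, 1]])]
    rep = evaluate_masks(gts, gts, [0, 1, 2])
    for vals in rep.per_class.values():
        assert all(v == 1.0 for v in vals.values())
    assert rep.micro["pixel_accuracy"] == 1.0


def test_evaluate_masks_single_image_consistency(rng):
    pred = rng.integers(0, 3, size=(10, 10))
    gt = rng.integers(0, 3, size=(10, 10))
    rep = evaluate_masks([pred], [gt], [1])
    assert rep.per_class[1]["dice"] == pytest.approx(dice(pred, gt, 1), abs=1e-12)
    assert rep.per_class[1]["iou"] == pytest.approx(iou(pred, gt, 1), abs=1e-12)


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        evaluate_masks([np.zeros((2, 2), int)], [], [0])


# ---- lesion geometry -------------------------------------------------------

def _disk_mask(radius, center=(64, 64), shape=(128, 128), cid=1):
    m = np.zeros(shape, dtype=int)
    rr, cc = draw.disk(center, radius, shape=shape)
    m[rr, cc] = cid
    return m


def test_geometry_rmse_zero_for_identical_masks():
    gt = _disk_mask(15)
    res = lesion_geometry_rmse([gt], [gt], 1, mode="diameter")
    assert res.rmse == pytest.approx(0.0, abs=1e-12)
    assert res.n_missed == 0


def test_geometry_rmse_disk_pair_diameter():
    # pred diameter 40, gt diameter 50 -> RMSE 10 within rasterisation tolerance
    pred = _disk_mask(20)
    gt = _disk_mask(25)
    res = lesion_geometry_rmse([pred], [gt], 1, mode="diameter")
    assert res.rmse == pytest.approx(10.0, abs=0.5)


def test_geometry_circumference_of_perfect_disk():
    gt = _disk_mask(20)
    res = lesion_geometry_rmse([gt], [gt], 1, mode="circumference")
    assert res.table["gt_measure"].iloc[0] == pytest.approx(2 * np.pi * 20,
                                                            rel=0.03)


def test_missed_lesion_contributes_full_measurement():
    gt = _disk_mask(10)
    pred = np.zeros_like(gt)
    res = lesion_geometry_rmse([pred], [gt], 1, mode="diameter")
    assert res.n_missed == 1
    d_true = np.sqrt(4 * (gt == 1).sum() / np.pi)
    assert res.rmse == pytest.approx(d_true, rel=1e-6)


def test_geometry_rmse_monotone_under_erosion():
    from scipy import ndimage
    gt = _disk_mask(20)
    errors = []
    pred = gt.copy()
    for _ in range(4):
        res = lesion_geometry_rmse([pred], [gt], 1, mode="diameter")
        errors.append(res.rmse)
        pred = ndimage.binary_erosion(pred == 1, iterations=2).astype(int)
    assert all(a <= b + 1e-9 for a, b in zip(errors, errors[1:]))


def test_geometry_empty_reference_gives_explicit_empty_result():
    empty = np.zeros((16, 16), dtype=int)
    res = lesion_geometry_rmse([empty], [empty], 1)
    assert res.rmse is None
    assert res.n_lesions == 0


def test_geometry_matching_prefers_largest_overlap():
    # one gt lesion overlapped by two pred components: match the bigger overlap
    gt = np.zeros((20, 20), int)
    gt[5:15, 5:15] = 1                      # 10x10 gt lesion
    pred = np.zeros((20, 20), int)
    pred[5:15, 5:12] = 1                    # big overlap (70 px)
    pred[5:15, 14:16] = 1                   # small overlap (10 px), separate comp
    res = lesion_geometry_rmse([pred], [gt], 1, mode="diameter")
    assert res.n_lesions == 1
    big_d = np.sqrt(4 * 70 / np.pi)
    assert res.table["pred_measure"].iloc[0] == pytest.approx(big_d, rel=1e-6)


# ---- property tests (hypothesis) ------------------------------------------

from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    pred=hnp.arrays(np.int64, (6, 6), elements=st.integers(0, 2)),
    gt=hnp.arrays(np.int64, (6, 6), elements=st.integers(0, 2)),
)
def test_dice_iou_identity_property(pred, gt):
    for cid in (0, 1, 2):
        j = iou(pred, gt, cid)
        assert abs(dice(pred, gt, cid) - 2 * j / (1 + j)) < 1e-12
        assert 0.0 <= j <= 1.0


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    pred=hnp.arrays(np.int64, (5, 5), elements=st.integers(0, 2)),
    gt=hnp.arrays(np.int64, (5, 5), elements=st.integers(0, 2)),
)
def test_micro_recall_equals_accuracy_on_reference_lesion_pixels(pred, gt):
    # pooled lesion recall == fraction of reference lesion pixels predicted
    # with the correct lesion class (definitional identity, binary task)
    lesion_pred = pred == 2
    lesion_gt = gt == 2
    rep = evaluate_masks([np.where(pred == 2, 1, 0)], [np.where(gt == 2, 1, 0)], [1])
    if lesion_gt.sum() == 0:
        return
    expected = (lesion_pred & lesion_gt).sum() / lesion_gt.sum()
    assert rep.per_class[1]["recall"] == pytest.approx(expected, abs=1e-12)
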