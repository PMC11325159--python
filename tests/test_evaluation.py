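"""Label matching, confusion metrics, SNR/PSNR, PRI."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybriseg import (
    ConfusionCounts,
    binary_metrics,
    confusion,
    evaluate,
    match_labels,
    micro_confusion,
    pri,
    snr_psnr,
)

from conftest import rand_index_by_pairs


def test_match_labels_identity_and_permutation():
    gt = np.array([[0, 0, 1], [2, 2, 1]])
    assert match_labels(gt, gt) == {0: 0, 1: 1, 2: 2}
    pred = np.array([[5, 5, 3], [9, 9, 3]])
    assert match_labels(pred, gt) == {5: 0, 3: 1, 9: 2}


def test_match_labels_majority_vote():
    gt = np.array([[0] * 6 + [1] * 4])
    pred = np.zeros((1, 10), dtype=int)  # one predicted segment over a 60/40 split
    assert match_labels(pred, gt) == {0: 0}


def test_confusion_perfect_prediction():
    gt = np.array([[0, 1], [1, 0]])
    c = confusion(gt, gt, positive_class=1)
    assert (c.fp, c.fn) == (0, 0)
    assert c.total == 4


def test_confusion_all_positive_half_gt():
    gt = np.zeros((10, 10), dtype=int)
    gt[:, 5:] = 1
    pred = np.ones((10, 10), dtype=int)
    # already in the gt vocabulary: everything predicted positive
    c = confusion(pred, gt, positive_class=1, matched=True)
    assert (c.tp, c.fp, c.tn, c.fn) == (50, 50, 0, 0)
    # with majority matching, the lone segment maps to gt 0 on the 50/50 tie
    c = confusion(pred, gt, positive_class=1)
    assert (c.tp, c.fp, c.tn, c.fn) == (0, 0, 50, 50)


def test_confusion_unknown_class_raises():
    gt = np.zeros((2, 2), dtype=int)
    with pytest.raises(ValueError, match="positive_class"):
        confusion(gt, gt, positive_class=7)


def test_metrics_perfect_case():
    r = binary_metrics(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
    for name in ("accuracy", "precision", "f_measure", "jaccard", "dice",
                 "specificity", "mcc"):
        assert getattr(r, name) == 1.0


def test_metrics_worked_example():
    # independent arithmetic: TP=6 TN=3 FP=1 FN=2
    r = binary_metrics(ConfusionCounts(6, 3, 1, 2))
    assert r.accuracy == pytest.approx(9 / 12)
    assert r.f_measure == pytest.approx(12 / 15)
    assert r.dice == pytest.approx(12 / 15)
    assert r.jaccard == pytest.approx(6 / 9)
    assert r.mcc == pytest.approx(16 / math.sqrt(1120))
    assert r.precision == pytest.approx(6 / 7)
    assert r.specificity == pytest.approx(3 / 4)


def test_specificity_paper_variant():
    r = binary_metrics(ConfusionCounts(6, 3, 1, 2), paper_formulas=True)
    assert r.specificity == pytest.approx(3 / 5)  # TN/(TN+FN)


def test_empty_denominator_conventions():
    r = binary_metrics(ConfusionCounts(0, 10, 0, 0))
    assert r.precision == 1.0 and r.jaccard == 1.0 and r.dice == 1.0
    assert r.mcc == 0.0
    assert any("precision" in f for f in r.flags)
    assert any("mcc" in f for f in r.flags)


@settings(max_examples=100, derandomize=True)
@given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
def test_dice_jaccard_identity(tp, tn, fp, fn):
    r = binary_metrics(ConfusionCounts(tp, tn, fp, fn))
    assert r.dice == pytest.approx(2 * r.jaccard / (1 + r.jaccard))


@settings(max_examples=50, derandomize=True)
@given(st.integers(1, 50), st.integers(1, 50), st.integers(0, 50), st.integers(0, 50))
def test_mcc_symmetric_under_class_swap(tp, tn, fp, fn):
    a = binary_metrics(ConfusionCounts(tp, tn, fp, fn)).mcc
    b = binary_metrics(ConfusionCounts(tn, tp, fn, fp)).mcc
    assert a == pytest.approx(b)


def test_metrics_bounded(rng):
    for _ in range(50):
        tp, tn, fp, fn = rng.integers(0, 30, 4)
        r = binary_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
        for name in ("accuracy", "precision", "f_measure", "jaccard", "dice",
                     "specificity"):
            assert 0.0 <= getattr(r, name) <= 1.0
        assert -1.0 <= r.mcc <= 1.0


def test_snr_psnr_closed_forms():
    a = np.zeros((4, 4, 3), np.uint8)
    b = a.copy()
    snr, psnr = snr_psnr(a, b)
    assert math.isinf(snr) and math.isinf(psnr)
    # worst constant error: MSE = 255^2 -> PSNR = 0
    b = np.full((4, 4, 3), 255, np.uint8)
    _, psnr = snr_psnr(a, b)
    assert psnr == pytest.approx(0.0)
    # MSE = 1 -> PSNR = 10 log10(65025)
    a = np.full((4, 4, 3), 100, np.uint8)
    b = np.full((4, 4, 3), 101, np.uint8)
    _, psnr = snr_psnr(a, b)
    assert psnr == pytest.approx(10 * math.log10(255**2), abs=1e-9)


def test_pri_perfect_and_hand_example():
    gt = np.array([[0, 0], [0, 0]])
    pred = np.array([[1, 1], [2, 2]])
    assert pri(gt, [gt]) == 1.0
    # 6 pairs; pred agrees with the all-one-label gt on the 2 within-row pairs
    assert pri(pred, [gt]) == pytest.approx(2 / 6)


def test_pri_label_permutation_invariance(rng):
    pred = rng.integers(0, 4, (6, 6))
    gt = rng.integers(0, 3, (6, 6))
    relabeled = np.vectorize({0: 9, 1: 4, 2: 7, 3: 0}.get)(pred)
    assert pri(pred, [gt]) == pytest.approx(pri(relabeled, [gt]))


def test_pri_contingency_equals_pair_enumeration(rng):
    for _ in range(30):
        h, w = rng.integers(2, 9, 2)
        pred = rng.integers(0, 5, (h, w))
        gt = rng.integers(0, 5, (h, w))
        assert pri(pred, [gt]) == pytest.approx(rand_index_by_pairs(pred, gt))


def test_pri_averages_over_ground_truths(rng):
    pred = rng.integers(0, 3, (5, 5))
    g1 = rng.integers(0, 3, (5, 5))
    g2 = rng.integers(0, 3, (5, 5))
    assert pri(pred, [g1, g2]) == pytest.approx((pri(pred, [g1]) + pri(pred, [g2])) / 2)


def test_evaluate_full_report(rng):
    gt = np.zeros((8, 8), dtype=int)
    gt[:, 4:] = 1
    pred = gt.copy()
    pred[0, 0] = 1  # one mislabelled pixel
    orig = rng.integers(0, 255, (8, 8, 3)).astype(np.uint8)
    recon = orig.copy()
    recon[0, 0, 0] ^= 4
    rep = evaluate(pred, gt, original=orig, reconstructed=recon)
    assert 0.9 < rep.dice < 1.0
    assert 0.9 < rep.pri <= 1.0
    assert rep.psnr_db is not None and rep.psnr_db > 30
    d = rep.to_dict()
    assert set(d) >= {"accuracy", "dice", "mcc", "pri", "snr_db", "psnr_db", "flags"}


def test_micro_confusion_counts_sum_over_classes():
    gt = np.array([[0, 0, 1, 2]])
    c = micro_confusion(gt, gt)
    assert c.total == 3 * gt.size
    assert c.fp == 0 and c.fn == 0
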