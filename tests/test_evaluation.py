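"""Metric formulas against a direct-arithmetic oracle; ROC/AUC against the
pairwise Mann-Whitney estimator."""

import numpy as np
import pytest

from plantlnc.evaluation import ConfusionCounts, confusion, metrics, roc_curve
from plantlnc.labels import LNCRNA, MRNA


def direct_metrics(tp, tn, fp, fn):
    """Independent re-implementation of the five fractions."""
    out = {}
    out["sensitivity"] = tp / (tp + fn) if tp + fn else None
    out["specificity"] = tn / (fp + tn) if fp + tn else None
    out["accuracy"] = (tp + tn) / (tp + fp + tn + fn)
    out["precision"] = tp / (tp + fp) if tp + fp else None
    p, s = out["precision"], out["sensitivity"]
    out["f1"] = 2 * p * s / (p + s) if p is not None and s is not None and p + s > 0 else None
    return out


def pairwise_auc(scores, y):
    """O(n^2) Mann-Whitney estimator: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, t in zip(scores, y) if t == LNCRNA]
    neg = [s for s, t in zip(scores, y) if t == MRNA]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def test_worked_example():
    m = metrics(ConfusionCounts(tp=9, tn=8, fp=2, fn=1))
    assert m.sensitivity == pytest.approx(0.9)
    assert m.specificity == pytest.approx(0.8)
    assert m.accuracy == pytest.approx(0.85)
    assert m.precision == pytest.approx(9 / 11)
    assert m.f1 == pytest.approx(2 * (9 / 11) * 0.9 / ((9 / 11) + 0.9))


def test_undefined_markers_not_zero():
    m = metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=3))
    assert m.precision is None and m.f1 is None
    assert m.sensitivity == 0.0


def test_all_zero_counts_rejected():
    with pytest.raises(ValueError):
        metrics(ConfusionCounts(0, 0, 0, 0))
    with pytest.raises(ValueError):
        ConfusionCounts(-1, 0, 0, 0)


def test_random_count_tuples_match_formula_oracle():
    rng = np.random.default_rng(2024)
    for _ in range(500):
        tp, tn, fp, fn = (int(v) for v in rng.integers(0, 50, size=4))
        if tp + tn + fp + fn == 0:
            continue
        got = metrics(ConfusionCounts(tp, tn, fp, fn)).as_dict()
        assert got == pytest.approx(direct_metrics(tp, tn, fp, fn))


def test_confusion_tally_against_brute_force():
    rng = np.random.default_rng(5)
    labels = np.array([LNCRNA, MRNA])
    truth = list(labels[rng.integers(0, 2, size=1000)])
    pred = list(labels[rng.integers(0, 2, size=1000)])
    cc = confusion(truth, pred)
    assert cc.tp == sum(t == LNCRNA and p == LNCRNA for t, p in zip(truth, pred))
    assert cc.tn == sum(t == MRNA and p == MRNA for t, p in zip(truth, pred))
    assert cc.fp == sum(t == MRNA and p == LNCRNA for t, p in zip(truth, pred))
    assert cc.fn == sum(t == LNCRNA and p == MRNA for t, p in zip(truth, pred))
    assert cc.total == 1000


def test_confusion_degenerate_predictions():
    truth = [LNCRNA, LNCRNA, MRNA, MRNA, MRNA]
    cc = confusion(truth, [LNCRNA] * 5)
    assert (cc.tp, cc.tn, cc.fp, cc.fn) == (2, 0, 3, 0)
    cc = confusion(truth, truth)
    assert cc.fp == cc.fn == 0 and metrics(cc).accuracy == 1.0


def test_confusion_input_validation():
    with pytest.raises(ValueError):
        confusion([LNCRNA], [LNCRNA, MRNA])
    with pytest.raises(ValueError):
        confusion([LNCRNA], ["coding"])


def test_perfect_separation_auc():
    y = [LNCRNA] * 5 + [MRNA] * 5
    roc = roc_curve([0.9, 0.8, 0.85, 0.95, 0.7, 0.1, 0.2, 0.3, 0.15, 0.05], y)
    assert roc.auc == pytest.approx(1.0)


def test_tied_scores_give_diagonal():
    y = [LNCRNA, LNCRNA, MRNA, MRNA]
    roc = roc_curve([0.5] * 4, y)
    assert roc.auc == pytest.approx(0.5)
    assert roc.points[0] == (0.0, 0.0) and roc.points[-1] == (1.0, 1.0)


def test_roc_starts_at_origin_and_thresholds_descend():
    rng = np.random.default_rng(1)
    y = [LNCRNA] * 30 + [MRNA] * 30
    roc = roc_curve(rng.random(60), y)
    assert roc.points[0] == (0.0, 0.0) and roc.points[-1] == (1.0, 1.0)
    assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)
    assert np.isinf(roc.thresholds[0])
    assert np.all(np.diff(roc.thresholds) < 0)


@pytest.mark.parametrize("n,ties", [(50, False), (200, True)])
def test_trapezoid_auc_equals_pairwise_estimator(n, ties):
    rng = np.random.default_rng(n)
    for _ in range(20):
        y = [LNCRNA if v else MRNA for v in rng.integers(0, 2, size=n)]
        if len(set(y)) < 2:
            continue
        scores = rng.random(n)
        if ties:
            scores = np.round(scores, 1)
        roc = roc_curve(scores, y)
        assert roc.auc == pytest.approx(pairwise_auc(scores, y), abs=1e-12)


def test_reversed_scores_complement_auc():
    rng = np.random.default_rng(3)
    y = [LNCRNA] * 40 + [MRNA] * 60
    scores = rng.random(100)
    assert roc_curve(scores, y).auc == pytest.approx(
        1.0 - roc_curve(-scores, y).auc, abs=1e-12
    )


def test_single_class_rejected():
    with pytest.raises(ValueError):
        roc_curve([0.1, 0.2], [LNCRNA, LNCRNA])
    with pytest.raises(ValueError):
        roc_curve([np.nan, 0.2], [LNCRNA, MRNA])
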