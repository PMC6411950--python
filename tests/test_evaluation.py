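"""Metrics against exhaustive/hand-computed oracles."""

import numpy as np
import pytest

from conftest import make_window
from kmalpred.evaluation import (
    ConfusionCounts,
    auc01,
    compare_window_sizes,
    confusion_at_threshold,
    cross_validate,
    evaluate,
    learning_curve,
    metrics,
    roc_auc,
    threshold_at_specificity,
)
from kmalpred.records import NEGATIVE, POSITIVE


def brute_force_auc(scores, labels):
    """Pairwise rank statistic: P(s+ > s-) + 0.5 P(tie)."""
    s = np.asarray(scores)
    y = np.asarray(labels)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_confusion_hand_count_and_strict_boundary():
    counts = confusion_at_threshold([0.9, 0.6, 0.4, 0.1], [1, 0, 1, 0], 0.5)
    assert (counts.tp, counts.fp, counts.tn, counts.fn) == (1, 1, 1, 1)
    # a score exactly at the threshold is a negative call
    at = confusion_at_threshold([0.5], [1], 0.5)
    assert (at.tp, at.fn) == (0, 1)
    allpos = confusion_at_threshold([0.9, 0.8], [1, 1], 0.1)
    assert allpos.fn == 0 and allpos.fp == 0
    with pytest.raises(ValueError):
        confusion_at_threshold([], [], 0.5)


@pytest.mark.parametrize(
    "counts,expected",
    [
        (ConfusionCounts(25, 25, 25, 25), (0.5, 0.5, 0.5, 0.0)),
        (ConfusionCounts(10, 0, 10, 0), (1.0, 1.0, 1.0, 1.0)),
        (ConfusionCounts(3, 1, 5, 1), (0.8, 0.75, 5 / 6, 14 / 24)),
        (ConfusionCounts(0, 0, 10, 0), (1.0, 0.0, 1.0, 0.0)),  # zero-denominator
    ],
)
def test_metric_formulas_exact(counts, expected):
    assert metrics(counts) == pytest.approx(expected)


def test_mcc_sign_flips_when_calls_inverted():
    counts = ConfusionCounts(30, 5, 40, 10)
    flipped = ConfusionCounts(tp=10, fp=40, tn=5, fn=30)
    assert metrics(counts)[3] == pytest.approx(-metrics(flipped)[3])


def test_auc_examples_and_tie_convention():
    _, auc = roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
    assert auc == pytest.approx(0.75)
    _, perfect = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert perfect == 1.0
    _, ties = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
    assert ties == pytest.approx(0.5)
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


def test_auc_matches_exhaustive_pairwise_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(10, 500))
        scores = rng.choice(np.round(rng.random(20), 2), size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        points, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        assert points[0].tolist() == [0.0, 0.0] and points[-1].tolist() == [1.0, 1.0]
        assert np.all(np.diff(points[:, 0]) >= 0)


def test_auc01_hand_integrated_areas():
    diagonal = np.array([[0.0, 0.0], [1.0, 1.0]])
    assert auc01(diagonal) == pytest.approx(0.005)
    perfect = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    assert auc01(perfect) == pytest.approx(0.1)
    piecewise = np.array([[0.0, 0.0], [0.05, 0.6], [0.1, 0.8], [1.0, 1.0]])
    assert auc01(piecewise) == pytest.approx(0.05 * 0.3 + 0.05 * 0.7)
    assert auc01(piecewise, normalized=True) == pytest.approx(0.5)


def test_auc01_bounded_by_auc(rng):
    for _ in range(25):
        scores = rng.random(80)
        labels = rng.integers(0, 2, size=80)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        points, auc = roc_auc(scores, labels)
        a01 = auc01(points)
        assert a01 <= min(auc, 0.1) + 1e-12


def test_threshold_at_specificity_order_statistics():
    negatives = [i / 10 for i in range(1, 11)]
    scores = negatives + [0.95]
    labels = [0] * 10 + [1]
    t = threshold_at_specificity(scores, labels, 0.9)
    assert sum(s > t for s in negatives) == 1
    t_full = threshold_at_specificity(scores, labels, 1.0)
    assert t_full >= max(negatives)
    counts = confusion_at_threshold(scores, labels, t)
    _, _, sp, _ = metrics(counts)
    assert sp >= 0.9


def test_metrics_invariant_under_reordering(rng):
    scores = rng.random(60)
    labels = rng.integers(0, 2, size=60)
    labels[:3] = [1, 0, 1]
    perm = rng.permutation(60)
    r1 = evaluate(scores, labels, threshold=0.5)
    r2 = evaluate(scores[perm], labels[perm], threshold=0.5)
    assert r1.summary() == r2.summary()


# ---------------------------------------------------------------------------
# harnesses (fast surrogate method: score = fraction of G in the window)


def _g_fraction_method(train, val):
    return np.array([w.sequence.count("G") / w.width for w in val])


def test_cross_validate_covers_every_window(small_windows):
    scores, labels, folds = cross_validate(_g_fraction_method, small_windows,
                                           k=5, seed=0)
    assert len(scores) == len(small_windows)
    assert set(folds.tolist()) == set(range(5))
    _, auc = roc_auc(scores, labels)
    assert auc > 0.7  # G-content alone already separates planted data


def test_learning_curve_shapes_and_determinism(small_windows):
    table = learning_curve({"gfrac": _g_fraction_method}, small_windows,
                           fractions=(0.5, 1.0), k=4, seed=1)
    assert len(table) == 2
    assert table.loc[table.fraction == 1.0, "n_windows"].item() == len(small_windows)
    again = learning_curve({"gfrac": _g_fraction_method}, small_windows,
                           fractions=(0.5, 1.0), k=4, seed=1)
    assert table.equals(again)
    with pytest.raises(ValueError):
        learning_curve({"g": _g_fraction_method}, small_windows, fractions=(0.0,))


def test_compare_window_sizes_table(small_truth):
    from kmalpred.dataset import build_windows

    def builder(size):
        windows, _ = build_windows(small_truth.proteins, small_truth.sites,
                                   window=size)
        return windows

    table = compare_window_sizes(builder, _g_fraction_method,
                                 sizes=(15, 31), k=4, seed=0)
    assert list(table["window"]) == [15, 31]
    assert all(table["auc"] > 0.6)
    with pytest.raises(ValueError):
        compare_window_sizes(builder, _g_fraction_method, sizes=(16,), k=4)
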