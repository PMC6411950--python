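"""Performance assessment: confusion metrics, ROC/AUC, partial AUC at low
false-positive rate, operating-threshold selection, and the cross-validation
harnesses (learning curves, window-size comparison).

Conventions:

* a window is called positive iff its score is strictly greater than the
  threshold;
* AUC is the trapezoid area under the threshold-sweep ROC (equivalently the
  pairwise rank statistic with ties counted half);
* AUC01 is the unnormalized trapezoid area over FPR in [0, 0.1] with linear
  interpolation at FPR = 0.1, so its maximum is 0.1;
* MCC is defined as 0 when any factor of its denominator is 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .dataset import group_kfold
from .records import PeptideWindow

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    """Summary of one evaluation: threshold metrics plus ROC areas."""

    counts: ConfusionCounts
    ac: float
    sn: float
    sp: float
    mcc: float
    roc: np.ndarray  # (n, 2) columns FPR, TPR
    auc: float
    auc01: float
    threshold: float

    def summary(self) -> dict:
        return {
            "Ac": self.ac, "Sn": self.sn, "Sp": self.sp, "MCC": self.mcc,
            "AUC": self.auc, "AUC01": self.auc01, "threshold": self.threshold,
            "TP": self.counts.tp, "FP": self.counts.fp,
            "TN": self.counts.tn, "FN": self.counts.fn,
        }


def _check(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size == 0:
        raise ValueError("no scores to evaluate")
    if s.shape != y.shape:
        raise ValueError("scores and labels are misaligned")
    return s, y


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> ConfusionCounts:
    """Counts under the strict-greater call rule (score == threshold is a
    negative call)."""
    s, y = _check(scores, labels)
    called = s > threshold
    return ConfusionCounts(
        tp=int(np.sum(called & (y == 1))),
        fp=int(np.sum(called & (y == 0))),
        tn=int(np.sum(~called & (y == 0))),
        fn=int(np.sum(~called & (y == 1))),
    )


def metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """Accuracy, sensitivity, specificity and Matthews correlation."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    total = counts.total
    ac = (tp + tn) / total if total else 0.0
    sn = tp / (tp + fn) if (tp + fn) else 0.0
    sp = tn / (tn + fp) if (tn + fp) else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fn) * (tn + fp)
    if denom == 0:
        logger.debug("MCC denominator zero; returning 0 by convention")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    return ac, sn, sp, float(mcc)


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[np.ndarray, float]:
    """Threshold-sweep ROC points (FPR, TPR) and the trapezoid AUC.

    Tied scores collapse into single threshold steps, so ties contribute
    diagonal segments and count one half, matching the rank statistic
    P(score+ > score-) + 0.5 P(tie).
    """
    s, y = _check(scores, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def auc01(roc_points: np.ndarray, max_fpr: float = 0.1, normalized: bool = False) -> float:
    """Trapezoid area under the ROC restricted to FPR in [0, ``max_fpr``].

    Reported raw (maximum ``max_fpr``) unless ``normalized`` divides by the
    FPR span. The curve is linearly interpolated at the cut point.
    """
    pts = np.asarray(roc_points, dtype=float)
    fpr, tpr = pts[:, 0], pts[:, 1]
    if np.any(np.diff(fpr) < 0):
        raise ValueError("ROC FPR values must be non-decreasing")
    tpr_cut = float(np.interp(max_fpr, fpr, tpr))
    mask = fpr < max_fpr
    xs = np.append(fpr[mask], max_fpr)
    ys = np.append(tpr[mask], tpr_cut)
    area = float(np.trapezoid(ys, xs))
    return area / max_fpr if normalized else area


def threshold_at_specificity(
    scores: Sequence[float],
    labels: Sequence[int],
    target_sp: float = 0.90,
) -> float:
    """Smallest threshold achieving specificity >= ``target_sp`` under the
    strict-greater call rule."""
    s, y = _check(scores, labels)
    neg = np.sort(s[y == 0])
    if neg.size == 0:
        raise ValueError("threshold selection requires negative examples")
    m = int(np.ceil(target_sp * neg.size))
    if m > neg.size:
        logger.warning(
            "specificity %.3f unattainable with %d negatives; using max score",
            target_sp, neg.size,
        )
        return float(neg[-1])
    if m <= 0:
        return float(np.nextafter(neg[0], -np.inf))
    return float(neg[m - 1])


def evaluate(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: Optional[float] = None,
    target_sp: float = 0.90,
) -> EvalReport:
    """Full report; if no threshold is given, the specificity-``target_sp``
    operating point is computed from the scored data itself."""
    s, y = _check(scores, labels)
    if threshold is None:
        threshold = threshold_at_specificity(s, y, target_sp=target_sp)
    counts = confusion_at_threshold(s, y, threshold)
    ac, sn, sp, mcc = metrics(counts)
    points, auc = roc_auc(s, y)
    return EvalReport(
        counts=counts, ac=ac, sn=sn, sp=sp, mcc=mcc,
        roc=points, auc=auc, auc01=auc01(points), threshold=float(threshold),
    )


# ---------------------------------------------------------------------------
# cross-validation harnesses

# A "method" maps (train windows, eval windows) -> scores for the eval windows.
Method = Callable[[Sequence[PeptideWindow], Sequence[PeptideWindow]], np.ndarray]


def cross_validate(
    method: Method,
    windows: Sequence[PeptideWindow],
    k: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Protein-grouped k-fold CV; returns pooled out-of-fold scores, labels
    and fold ids, in a fixed window order."""
    folds = group_kfold(windows, k=k, seed=seed)
    scores, labels, fold_ids = [], [], []
    for f, (train, val) in enumerate(folds):
        s = np.asarray(method(train, val), dtype=float)
        if len(s) != len(val):
            raise ValueError("method returned misaligned scores")
        scores.append(s)
        labels.append([w.label for w in val])
        fold_ids.append(np.full(len(val), f))
    return np.concatenate(scores), np.concatenate(labels), np.concatenate(fold_ids)


def _subsample_by_protein(windows, fraction, rng) -> list[PeptideWindow]:
    ids = sorted({w.protein_id for w in windows})
    rng.shuffle(ids)
    n_keep = max(1, int(round(fraction * len(ids))))
    keep = set(ids[:n_keep])
    return [w for w in windows if w.protein_id in keep]


def learning_curve(
    methods: dict[str, Method],
    windows: Sequence[PeptideWindow],
    fractions: Sequence[float] = (1 / 8, 1 / 4, 1 / 2, 1.0),
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """CV performance of each method at protein-grouped subsamples of the
    training data; one row per (method, fraction)."""
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rows = []
    for fraction in sorted(fractions):
        rng = np.random.default_rng(seed)
        sub = windows if fraction == 1.0 else _subsample_by_protein(windows, fraction, rng)
        if len({w.protein_id for w in sub}) < k:
            raise ValueError(f"fraction {fraction} leaves fewer proteins than k={k}")
        for name, method in methods.items():
            s, y, _ = cross_validate(method, sub, k=k, seed=seed)
            points, auc = roc_auc(s, y)
            rows.append({
                "method": name, "fraction": fraction, "n_windows": len(sub),
                "auc": auc, "auc01": auc01(points),
            })
    return pd.DataFrame(rows)


def compare_window_sizes(
    dataset_builder: Callable[[int], Sequence[PeptideWindow]],
    method: Method,
    sizes: Sequence[int] = (15, 19, 23, 27, 31, 35),
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Rebuild the dataset at each window size and report CV AUC per size."""
    if any(size % 2 == 0 for size in sizes):
        raise ValueError("window sizes must be odd")
    rows = []
    for size in sizes:
        windows = dataset_builder(size)
        s, y, _ = cross_validate(method, windows, k=k, seed=seed)
        points, auc = roc_auc(s, y)
        rows.append({"window": size, "auc": auc, "auc01": auc01(points),
                     "n_windows": len(windows)})
    return pd.DataFrame(rows)
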