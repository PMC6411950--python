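"""Logistic integration of the recurrent and forest classifiers.

The final score S of the ensemble (LEMP-style integration) solves

    log S/(1-S) = w1*C1 + w2*C2 + b

where C1 is the recurrent model's probability score, C2 the forest's, and
(w1, w2, b) are fit by plain maximum-likelihood logistic regression of the
labels on out-of-fold component scores — each window must be scored by
component models that never saw it in training, otherwise the weights are
optimistically biased toward the more overfit component.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from .records import PeptideWindow


@dataclass
class ComponentScores:
    """Aligned per-window component scores with labels and fold bookkeeping."""

    c_deep: np.ndarray
    c_forest: np.ndarray
    labels: np.ndarray
    folds: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.c_deep = np.asarray(self.c_deep, dtype=float)
        self.c_forest = np.asarray(self.c_forest, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.labels)
        if len(self.c_deep) != n or len(self.c_forest) != n:
            raise ValueError("component scores and labels are misaligned")


@dataclass
class EnsembleModel:
    """Weights of the logistic combination; component order is fixed:
    w1 multiplies the deep model's score, w2 the forest's."""

    w1: float
    w2: float
    b: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.w1, self.w2, self.b])):
            raise ValueError("ensemble coefficients must be finite")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"w1": self.w1, "w2": self.w2, "b": self.b,
                       "component_order": ["deep", "forest"]}, fh, indent=2)

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(w1=d["w1"], w2=d["w2"], b=d["b"])


def fit_ensemble(scores: ComponentScores) -> EnsembleModel:
    """Maximum-likelihood logistic regression of label on (C1, C2).

    No regularization is applied; degenerate inputs (a constant component,
    or complete separation) raise rather than silently shrinking.
    """
    for name, c in (("deep", scores.c_deep), ("forest", scores.c_forest)):
        if np.ptp(c) == 0.0:
            raise ValueError(f"component {name!r} has constant scores; cannot fit")
    if len(np.unique(scores.labels)) < 2:
        raise ValueError("ensemble fitting needs both classes")
    X = sm.add_constant(np.column_stack([scores.c_deep, scores.c_forest]))
    try:
        result = sm.Logit(scores.labels, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels PerfectSeparationError et al.
        raise ValueError(f"logistic fit failed: {exc}") from exc
    params = result.params
    if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 1e6:
        raise ValueError("logistic fit diverged (scores may separate perfectly)")
    b, w1, w2 = params
    return EnsembleModel(w1=float(w1), w2=float(w2), b=float(b))


def predict_ensemble(model: EnsembleModel, c_deep, c_forest) -> np.ndarray:
    """S = sigmoid(w1*C1 + w2*C2 + b); accepts scalars or arrays."""
    z = model.w1 * np.asarray(c_deep, dtype=float) + \
        model.w2 * np.asarray(c_forest, dtype=float) + model.b
    return expit(z)


def oof_component_scores(
    deep_method,
    forest_method,
    windows: Sequence[PeptideWindow],
    k: int = 10,
    seed: int = 0,
) -> ComponentScores:
    """Score every window out-of-fold with both components on shared
    protein-grouped folds (see :func:`kmalpred.evaluation.cross_validate`)."""
    from .evaluation import cross_validate

    s1, y1, f1 = cross_validate(deep_method, windows, k=k, seed=seed)
    s2, y2, f2 = cross_validate(forest_method, windows, k=k, seed=seed)
    if not (np.array_equal(y1, y2) and np.array_equal(f1, f2)):
        raise RuntimeError("component CV folds diverged despite shared seed")
    return ComponentScores(c_deep=s1, c_forest=s2, labels=y1, folds=f1)


def write_predictions(
    path,
    windows: Sequence[PeptideWindow],
    score_deep: Sequence[float],
    score_forest: Sequence[float],
    score_ensemble: Sequence[float],
    threshold: float,
) -> None:
    """Prediction table: one row per window with all three scores and the
    thresholded call (strict-greater rule on the ensemble score)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([
            "protein_id", "position", "window",
            "score_lstm", "score_rf", "score_lemp",
            "predicted_label_at_threshold",
        ])
        for w, s1, s2, s in zip(windows, score_deep, score_forest, score_ensemble):
            writer.writerow([
                w.protein_id, w.center_position, w.sequence,
                f"{s1:.6f}", f"{s2:.6f}", f"{s:.6f}",
                "positive" if s > threshold else "negative",
            ])
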