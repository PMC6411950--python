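"""End-to-end glue: reusable CV "methods" for each classifier family and a
full predictor (forest + recurrent model + logistic ensemble + operating
threshold) that can be trained, saved, reloaded and applied to a proteome.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__ as _pkg_version
from .dataset import extract_window
from .encodings import eaac_matrix, onehot_tensor, token_matrix
from .ensemble import (
    ComponentScores,
    EnsembleModel,
    fit_ensemble,
    oof_component_scores,
    predict_ensemble,
)
from .evaluation import threshold_at_specificity
from .models import (
    DeepModelSpec,
    ForestModel,
    build_cnn_model,
    build_deep_model,
    load_model_bundle,
    predict_scores,
    save_model_bundle,
    train_deep,
    train_forest,
)
from .nn import TrainConfig
from .records import PeptideWindow, ProteinRecord

logger = logging.getLogger(__name__)


def _labels(windows: Sequence[PeptideWindow]) -> np.ndarray:
    return np.array([w.label for w in windows], dtype=int)


def rf_eaac_method(n_trees: int = 1000, slide: int = 8, seed: int = 0,
                   n_jobs: int = 1):
    """Forest-on-EAAC as a (train, eval) -> scores method."""

    def method(train, val):
        Xtr, names = eaac_matrix(train, slide=slide)
        model = train_forest(Xtr, _labels(train), names, n_trees=n_trees,
                             seed=seed, n_jobs=n_jobs)
        Xva, _ = eaac_matrix(val, slide=slide)
        return model.predict_scores(Xva)

    return method


def lstm_we_method(spec: Optional[DeepModelSpec] = None, epochs: int = 300,
                   batch_size: int = 512, learning_rate: float = 1e-3,
                   seed: int = 0):
    """Embedding-LSTM as a (train, eval) -> scores method."""

    def method(train, val):
        model = build_deep_model(spec or DeepModelSpec(), "embedding", seed=seed)
        cfg = TrainConfig(max_epochs=epochs, batch_size=batch_size,
                          learning_rate=learning_rate, seed=seed)
        train_deep(model, token_matrix(train), _labels(train), cfg)
        return model.predict(token_matrix(val))

    return method


def lstm_onehot_method(spec: Optional[DeepModelSpec] = None, epochs: int = 300,
                       batch_size: int = 512, learning_rate: float = 1e-3,
                       seed: int = 0):
    def method(train, val):
        model = build_deep_model(spec or DeepModelSpec(), "onehot", seed=seed)
        cfg = TrainConfig(max_epochs=epochs, batch_size=batch_size,
                          learning_rate=learning_rate, seed=seed)
        train_deep(model, onehot_tensor(train), _labels(train), cfg)
        return model.predict(onehot_tensor(val))

    return method


def cnn_we_method(epochs: int = 300, batch_size: int = 512,
                  learning_rate: float = 1e-3, seed: int = 0, **cnn_kwargs):
    def method(train, val):
        model = build_cnn_model(seed=seed, **cnn_kwargs)
        cfg = TrainConfig(max_epochs=epochs, batch_size=batch_size,
                          learning_rate=learning_rate, seed=seed)
        train_deep(model, token_matrix(train), _labels(train), cfg)
        return model.predict(token_matrix(val))

    return method


@dataclass
class Predictor:
    """The trained ensemble predictor: both components, the logistic
    combination, and the stored specificity-90% operating threshold."""

    forest: ForestModel
    deep: object  # LSTMNet
    ensemble: EnsembleModel
    threshold: float
    slide: int = 8
    window: int = 31
    metadata: Optional[dict] = None

    def score_windows(self, windows: Sequence[PeptideWindow]):
        """Per-window (deep, forest, ensemble) scores."""
        X, _ = eaac_matrix(windows, slide=self.slide)
        s_forest = self.forest.predict_scores(X)
        s_deep = self.deep.predict(token_matrix(windows))
        s_ens = predict_ensemble(self.ensemble, s_deep, s_forest)
        return s_deep, s_forest, s_ens

    def predict_proteins(self, proteins: Sequence[ProteinRecord]):
        """Score every lysine of every protein; returns (windows, scores)."""
        windows = []
        for p in proteins:
            for i, ch in enumerate(p.sequence):
                if ch == "K":
                    windows.append(extract_window(p, i + 1, window=self.window))
        if not windows:
            logger.warning("no lysine residues found; nothing to predict")
            return [], (np.array([]), np.array([]), np.array([]))
        return windows, self.score_windows(windows)

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_model_bundle(self.forest, directory / "rf_eaac")
        save_model_bundle(self.deep, directory / "lstm_we")
        self.ensemble.save(directory / "ensemble.json")
        meta = dict(self.metadata or {})
        meta.update({
            "threshold": self.threshold, "slide": self.slide,
            "window": self.window, "package_version": _pkg_version,
        })
        with open(directory / "predictor.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
        return directory

    @classmethod
    def load(cls, directory) -> "Predictor":
        directory = Path(directory)
        forest, _ = load_model_bundle(directory / "rf_eaac")
        deep, _ = load_model_bundle(directory / "lstm_we")
        ens = EnsembleModel.load(directory / "ensemble.json")
        with open(directory / "predictor.json") as fh:
            meta = json.load(fh)
        return cls(forest=forest, deep=deep, ensemble=ens,
                   threshold=meta["threshold"], slide=meta["slide"],
                   window=meta["window"], metadata=meta)


def train_predictor(
    windows: Sequence[PeptideWindow],
    k: int = 10,
    seed: int = 0,
    n_trees: int = 1000,
    epochs: int = 300,
    batch_size: int = 512,
    learning_rate: float = 1e-3,
    slide: int = 8,
    spec: Optional[DeepModelSpec] = None,
    target_sp: float = 0.90,
) -> tuple[Predictor, ComponentScores]:
    """Train the full ensemble predictor on a window dataset.

    The logistic weights are fit on pooled out-of-fold component scores from
    protein-grouped k-fold CV; the final component models are then retrained
    on all windows, and the default operating threshold is the ensemble
    score achieving specificity ``target_sp`` on the out-of-fold scores.
    Returns the predictor and the out-of-fold scores (useful for reporting).
    """
    spec = spec or DeepModelSpec()
    deep_m = lstm_we_method(spec=spec, epochs=epochs, batch_size=batch_size,
                            learning_rate=learning_rate, seed=seed)
    rf_m = rf_eaac_method(n_trees=n_trees, slide=slide, seed=seed)
    oof = oof_component_scores(deep_m, rf_m, windows, k=k, seed=seed)
    ens = fit_ensemble(oof)
    oof_ens = predict_ensemble(ens, oof.c_deep, oof.c_forest)
    threshold = threshold_at_specificity(oof_ens, oof.labels, target_sp=target_sp)

    y = _labels(windows)
    Xtr, names = eaac_matrix(windows, slide=slide)
    forest = train_forest(Xtr, y, names, n_trees=n_trees, seed=seed)
    deep = build_deep_model(spec, "embedding", seed=seed)
    cfg = TrainConfig(max_epochs=epochs, batch_size=batch_size,
                      learning_rate=learning_rate, seed=seed)
    train_deep(deep, token_matrix(windows), y, cfg)

    meta = {"seed": seed, "k": k, "n_trees": n_trees, "epochs": epochs,
            "batch_size": batch_size, "target_sp": target_sp,
            "n_windows": len(windows), "n_positive": int(y.sum())}
    return Predictor(forest=forest, deep=deep, ensemble=ens,
                     threshold=threshold, slide=slide,
                     window=windows[0].width, metadata=meta), oof
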