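"""Classifier layer: random forests on feature vectors and the recurrent /
convolutional sequence models, with a shared score-in-[0,1] contract and a
versioned on-disk bundle format.

Three families are provided:

* ``ForestModel`` — 1000-tree random forest (sklearn) on any encoding,
  canonically EAAC; the prediction score is the mean per-tree probability
  (a Weka-style vote fraction is available via ``score_mode='vote'``);
* LSTM with a learned 21x5 residue embedding (``build_deep_model`` in
  ``embedding`` mode) or consuming one-hot rows (``onehot`` mode);
* the convolutional variant (``build_cnn_model``).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .alphabet import ALPHABET
from .nn import ConvNet, LSTMNet, TrainConfig, train as _nn_train

BUNDLE_VERSION = 1


@dataclass
class DeepModelSpec:
    """Architecture of the recurrent classifier (defaults are the published
    configuration: 5-dim embedding over 21 symbols, 32 LSTM units, 128-unit
    ReLU dense layer, 20% dropout after the recurrent and dense layers)."""

    vocab_size: int = 21
    embed_dim: int = 5
    lstm_units: int = 32
    dense_units: int = 128
    dropout_rate: float = 0.2
    input_length: int = 31

    def __post_init__(self) -> None:
        if min(self.vocab_size, self.embed_dim, self.lstm_units, self.dense_units,
               self.input_length) < 1:
            raise ValueError("all architecture dimensions must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class EmbeddingMatrix:
    """Learned residue word-vectors: one row per alphabet symbol (21 x 5)."""

    symbols: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.symbols):
            raise ValueError("one row per symbol required")

    def residue_rows(self) -> "EmbeddingMatrix":
        """The 20 amino-acid rows (gap dropped), for residue clustering."""
        keep = [i for i, s in enumerate(self.symbols) if s != "-"]
        return EmbeddingMatrix(
            symbols=[self.symbols[i] for i in keep], matrix=self.matrix[keep]
        )


class ForestModel:
    """Random forest with named features and a [0,1] score contract."""

    kind = "forest"

    def __init__(self, estimator: RandomForestClassifier,
                 feature_names: list[str], metadata: dict, score_mode: str = "proba"):
        self.estimator = estimator
        self.feature_names = list(feature_names)
        self.metadata = dict(metadata)
        self.score_mode = score_mode

    @property
    def n_trees(self) -> int:
        return self.estimator.n_estimators

    def predict_scores(
        self, X: np.ndarray, feature_names: Optional[Sequence[str]] = None
    ) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature matrix has {X.shape[-1] if X.ndim == 2 else '?'} columns, "
                f"model expects {len(self.feature_names)}"
            )
        if feature_names is not None and list(feature_names) != self.feature_names:
            raise ValueError("feature names do not match the training encoding")
        if self.score_mode == "vote":
            pos = self.estimator.classes_.tolist().index(1)
            votes = np.mean(
                [(t.predict(X) == pos) for t in self.estimator.estimators_], axis=0
            )
            return votes.astype(float)
        proba = self.estimator.predict_proba(X)
        pos = self.estimator.classes_.tolist().index(1)
        return proba[:, pos]


def train_forest(
    X: np.ndarray,
    labels: Sequence[int],
    feature_names: Sequence[str],
    n_trees: int = 1000,
    seed: int = 0,
    max_features: Union[str, int, float] = "sqrt",
    score_mode: str = "proba",
    n_jobs: int = 1,
) -> ForestModel:
    """Fit the forest classifier; reproducible from ``seed``.

    ``max_features='sqrt'`` is the per-split candidate count; pass 1.0 to use
    every feature at every split (bagged unrandomized trees).
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(feature_names):
        raise ValueError("feature_names length does not match matrix width")
    est = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        random_state=seed,
        n_jobs=n_jobs,
    )
    est.fit(X, y)
    meta = {"seed": seed, "n_trees": n_trees, "max_features": str(max_features)}
    return ForestModel(est, list(feature_names), meta, score_mode=score_mode)


def build_deep_model(
    spec: DeepModelSpec = DeepModelSpec(),
    input_mode: str = "embedding",
    seed: int = 0,
) -> LSTMNet:
    """Untrained recurrent classifier in embedding or one-hot input mode."""
    return LSTMNet(
        input_mode=input_mode,
        vocab_size=spec.vocab_size,
        embed_dim=spec.embed_dim,
        lstm_units=spec.lstm_units,
        dense_units=spec.dense_units,
        dropout_rate=spec.dropout_rate,
        input_length=spec.input_length,
        seed=seed,
    )


def build_cnn_model(
    embed_dim: int = 5,
    n_conv_layers: int = 4,
    n_filters: int = 64,
    kernel_size: int = 5,
    dropout_rate: float = 0.2,
    input_length: int = 31,
    seed: int = 0,
) -> ConvNet:
    """Untrained convolutional classifier (embedding input, four 1-D
    convolution layers, global max pool, logistic output)."""
    return ConvNet(
        embed_dim=embed_dim,
        n_conv_layers=n_conv_layers,
        n_filters=n_filters,
        kernel_size=kernel_size,
        dropout_rate=dropout_rate,
        input_length=input_length,
        seed=seed,
    )


def train_deep(model, X, labels, cfg: TrainConfig,
               X_val=None, y_val=None) -> list[float]:
    """Train a deep model in place; returns the epoch loss history."""
    return _nn_train(model, np.asarray(X), np.asarray(labels, dtype=float), cfg,
                     X_val=X_val, y_val=y_val)


def predict_scores(model, inputs) -> np.ndarray:
    """Uniform scoring entry point across model families."""
    if isinstance(model, ForestModel):
        return model.predict_scores(inputs)
    return model.predict(np.asarray(inputs))


def extract_embedding(model) -> EmbeddingMatrix:
    """The learned residue word-vector matrix of an embedding-mode model."""
    E = model.embedding_matrix()
    return EmbeddingMatrix(symbols=list(ALPHABET), matrix=E)


# ---------------------------------------------------------------------------
# persistence


def save_model_bundle(model, directory, extra_metadata: Optional[dict] = None) -> Path:
    """Write a model + metadata bundle; returns the directory path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "bundle_version": BUNDLE_VERSION,
        "kind": model.kind,
        "alphabet": ALPHABET,
    }
    if extra_metadata:
        meta.update(extra_metadata)
    if isinstance(model, ForestModel):
        meta["feature_names"] = model.feature_names
        meta["score_mode"] = model.score_mode
        meta["model_metadata"] = model.metadata
        joblib.dump(model.estimator, directory / "forest.joblib")
    else:
        meta["config"] = model.config
        np.savez(directory / "weights.npz", **model.params)
    with open(directory / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return directory


def load_model_bundle(directory):
    directory = Path(directory)
    with open(directory / "metadata.json") as fh:
        meta = json.load(fh)
    if meta["alphabet"] != ALPHABET:
        raise ValueError("bundle was trained under a different alphabet order")
    kind = meta["kind"]
    if kind == "forest":
        est = joblib.load(directory / "forest.joblib")
        return ForestModel(
            est, meta["feature_names"], meta.get("model_metadata", {}),
            score_mode=meta.get("score_mode", "proba"),
        ), meta
    cfg = meta["config"]
    if kind == "lstm":
        model = LSTMNet(**cfg)
    elif kind == "cnn":
        model = ConvNet(**cfg)
    else:
        raise ValueError(f"unknown bundle kind {kind!r}")
    with np.load(directory / "weights.npz") as npz:
        model.params = {k: npz[k].copy() for k in npz.files}
    return model, meta
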