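"""A small, deterministic neural-network engine for the sequence classifiers.

Implements exactly the architectures this package needs, in double-precision
numpy with hand-written backpropagation:

* ``LSTMNet`` — embedding (or one-hot input) -> single LSTM layer -> dropout
  -> dense ReLU layer -> dropout -> logistic output;
* ``ConvNet`` — embedding -> four 1-D convolution layers (ReLU, same
  padding) -> global max pool -> dropout -> logistic output.

Training uses minibatch Adam on the binary cross-entropy, computed on logits
for numerical stability. Everything (initialization, batch order, dropout
masks) derives from explicit seeds, so runs are bit-reproducible, and
gradients are verified against finite differences in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_from_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z = logits.ravel()
    y = y.ravel().astype(float)
    loss = float(np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (_sigmoid(z) - y) / len(z)
    return loss, dz.reshape(logits.shape)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _dropout_mask(rng: np.random.Generator, shape, rate: float) -> np.ndarray:
    keep = 1.0 - rate
    return (rng.random(shape) < keep) / keep


@dataclass
class TrainConfig:
    """Optimization settings (defaults follow the published training regimen:
    binary cross-entropy with Adam, up to 300 epochs, batches of 512,
    20% dropout)."""

    max_epochs: int = 300
    batch_size: int = 512
    learning_rate: float = 1e-3
    seed: int = 0
    patience: Optional[int] = None  # early stop on validation loss if set

    def __post_init__(self) -> None:
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be >= 1")


class LSTMNet:
    """Recurrent classifier over a peptide window.

    ``input_mode='embedding'`` consumes integer token sequences through a
    learned (vocab x embed_dim) embedding; ``input_mode='onehot'`` consumes
    rows of a (W x 20) one-hot matrix directly.
    """

    kind = "lstm"

    def __init__(
        self,
        input_mode: str = "embedding",
        vocab_size: int = 21,
        embed_dim: int = 5,
        lstm_units: int = 32,
        dense_units: int = 128,
        dropout_rate: float = 0.2,
        input_length: int = 31,
        onehot_dim: int = 20,
        seed: int = 0,
    ):
        if input_mode not in ("embedding", "onehot"):
            raise ValueError("input_mode must be 'embedding' or 'onehot'")
        if not 0.0 <= dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        self.config = dict(
            input_mode=input_mode, vocab_size=vocab_size, embed_dim=embed_dim,
            lstm_units=lstm_units, dense_units=dense_units,
            dropout_rate=dropout_rate, input_length=input_length,
            onehot_dim=onehot_dim, seed=seed,
        )
        rng = np.random.default_rng(seed)
        D = embed_dim if input_mode == "embedding" else onehot_dim
        H = lstm_units
        self.params: dict[str, np.ndarray] = {}
        if input_mode == "embedding":
            self.params["E"] = rng.normal(0.0, 0.1, size=(vocab_size, embed_dim))
        self.params["Wx"] = _glorot(rng, (D, 4 * H))
        self.params["Wh"] = _glorot(rng, (H, 4 * H))
        self.params["b"] = np.zeros(4 * H)
        self.params["b"][H : 2 * H] = 1.0  # forget-gate bias
        self.params["W1"] = _glorot(rng, (H, dense_units))
        self.params["b1"] = np.zeros(dense_units)
        self.params["W2"] = _glorot(rng, (dense_units, 1))
        self.params["b2"] = np.zeros(1)

    # -- forward -----------------------------------------------------------

    def forward(self, X: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None):
        p = self.params
        H = self.config["lstm_units"]
        rate = self.config["dropout_rate"]
        if self.config["input_mode"] == "embedding":
            tokens = np.asarray(X, dtype=np.int64)
            inp = p["E"][tokens]  # (B, T, D)
        else:
            tokens = None
            inp = np.asarray(X, dtype=float)
        B, T, D = inp.shape
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        for t in range(T):
            x_t = inp[:, t, :]
            z = x_t @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            steps.append((x_t, h, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
        if train and rate > 0:
            m0 = _dropout_mask(rng, h.shape, rate)
            h_d = h * m0
        else:
            m0, h_d = None, h
        a1_pre = h_d @ p["W1"] + p["b1"]
        a1 = np.maximum(a1_pre, 0.0)
        if train and rate > 0:
            m1 = _dropout_mask(rng, a1.shape, rate)
            a1_d = a1 * m1
        else:
            m1, a1_d = None, a1
        logits = a1_d @ p["W2"] + p["b2"]
        cache = (tokens, inp, steps, h, m0, h_d, a1_pre, a1, m1, a1_d)
        return logits, cache

    # -- backward ----------------------------------------------------------

    def backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        p = self.params
        H = self.config["lstm_units"]
        tokens, inp, steps, h_last, m0, h_d, a1_pre, a1, m1, a1_d = cache
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        grads["W2"] = a1_d.T @ dlogits
        grads["b2"] = dlogits.sum(axis=0)
        da1 = dlogits @ p["W2"].T
        if m1 is not None:
            da1 = da1 * m1
        da1_pre = da1 * (a1_pre > 0)
        grads["W1"] = h_d.T @ da1_pre
        grads["b1"] = da1_pre.sum(axis=0)
        dh = da1_pre @ p["W1"].T
        if m0 is not None:
            dh = dh * m0

        dinp = np.zeros_like(inp)
        dc = np.zeros((inp.shape[0], H))
        for t in range(len(steps) - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c_new, tc = steps[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            grads["Wx"] += x_t.T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dinp[:, t, :] = dz @ p["Wx"].T
            dh = dz @ p["Wh"].T
            dc = dc * f
        if self.config["input_mode"] == "embedding":
            dE = np.zeros_like(p["E"])
            np.add.at(dE, tokens.ravel(), dinp.reshape(-1, dinp.shape[-1]))
            grads["E"] = dE
        return grads

    def predict(self, X: np.ndarray, batch_size: int = 2048) -> np.ndarray:
        """Probability scores in (0, 1); dropout disabled, order-preserving."""
        out = []
        for s in range(0, len(X), batch_size):
            logits, _ = self.forward(X[s : s + batch_size], train=False)
            out.append(_sigmoid(logits).ravel())
        return np.concatenate(out)

    def embedding_matrix(self) -> np.ndarray:
        if self.config["input_mode"] != "embedding":
            raise ValueError("model was built in one-hot mode; it has no embedding")
        return self.params["E"].copy()


class ConvNet:
    """Convolutional counterpart: embedding, four 1-D convolution layers,
    global max pooling, dropout, logistic output."""

    kind = "cnn"

    def __init__(
        self,
        vocab_size: int = 21,
        embed_dim: int = 5,
        n_conv_layers: int = 4,
        n_filters: int = 64,
        kernel_size: int = 5,
        dropout_rate: float = 0.2,
        input_length: int = 31,
        seed: int = 0,
    ):
        self.config = dict(
            vocab_size=vocab_size, embed_dim=embed_dim, n_conv_layers=n_conv_layers,
            n_filters=n_filters, kernel_size=kernel_size, dropout_rate=dropout_rate,
            input_length=input_length, seed=seed,
        )
        rng = np.random.default_rng(seed)
        self.params = {"E": rng.normal(0.0, 0.1, size=(vocab_size, embed_dim))}
        c_in = embed_dim
        for l in range(n_conv_layers):
            self.params[f"W{l}"] = _glorot(rng, (kernel_size * c_in, n_filters)).reshape(
                kernel_size, c_in, n_filters
            )
            self.params[f"c{l}"] = np.zeros(n_filters)
            c_in = n_filters
        self.params["Wo"] = _glorot(rng, (c_in, 1))
        self.params["bo"] = np.zeros(1)

    def _conv_forward(self, X: np.ndarray, W: np.ndarray, b: np.ndarray):
        K = W.shape[0]
        pad = K // 2
        Xp = np.pad(X, ((0, 0), (pad, pad), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(Xp, K, axis=1)  # (B,T,C,K)
        pre = np.einsum("btck,kco->bto", win, W) + b
        return pre, Xp

    def forward(self, tokens: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None):
        p = self.params
        L = self.config["n_conv_layers"]
        rate = self.config["dropout_rate"]
        tokens = np.asarray(tokens, dtype=np.int64)
        X = p["E"][tokens]
        caches = []
        for l in range(L):
            pre, Xp = self._conv_forward(X, p[f"W{l}"], p[f"c{l}"])
            act = np.maximum(pre, 0.0)
            caches.append((Xp, pre))
            X = act
        pooled_idx = np.argmax(X, axis=1)  # (B, C)
        pooled = np.take_along_axis(X, pooled_idx[:, None, :], axis=1)[:, 0, :]
        if train and rate > 0:
            mask = _dropout_mask(rng, pooled.shape, rate)
            pooled_d = pooled * mask
        else:
            mask, pooled_d = None, pooled
        logits = pooled_d @ p["Wo"] + p["bo"]
        cache = (tokens, caches, X, pooled_idx, mask, pooled_d)
        return logits, cache

    def backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        p = self.params
        L = self.config["n_conv_layers"]
        K = self.config["kernel_size"]
        pad = K // 2
        tokens, caches, last_act, pooled_idx, mask, pooled_d = cache
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["Wo"] = pooled_d.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dpooled = dlogits @ p["Wo"].T
        if mask is not None:
            dpooled = dpooled * mask
        dX = np.zeros_like(last_act)
        np.put_along_axis(dX, pooled_idx[:, None, :], dpooled[:, None, :], axis=1)
        for l in range(L - 1, -1, -1):
            Xp, pre = caches[l]
            dpre = dX * (pre > 0)
            win = np.lib.stride_tricks.sliding_window_view(Xp, K, axis=1)
            grads[f"W{l}"] = np.einsum("btck,bto->kco", win, dpre)
            grads[f"c{l}"] = dpre.sum(axis=(0, 1))
            dXp = np.zeros_like(Xp)
            W = p[f"W{l}"]
            for kk in range(K):
                dXp[:, kk : kk + dX.shape[1], :] += dpre @ W[kk].T
            dX = dXp[:, pad : Xp.shape[1] - pad, :]
        dE = np.zeros_like(p["E"])
        np.add.at(dE, tokens.ravel(), dX.reshape(-1, dX.shape[-1]))
        grads["E"] = dE
        return grads

    def predict(self, X: np.ndarray, batch_size: int = 2048) -> np.ndarray:
        out = []
        for s in range(0, len(X), batch_size):
            logits, _ = self.forward(X[s : s + batch_size], train=False)
            out.append(_sigmoid(logits).ravel())
        return np.concatenate(out)

    def embedding_matrix(self) -> np.ndarray:
        return self.params["E"].copy()


def train(
    model,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    X_val: Optional[np.ndarray] = None,
    y_val: Optional[np.ndarray] = None,
) -> list[float]:
    """Minibatch Adam training; returns the per-epoch mean training loss.

    With a validation set and ``cfg.patience``, training stops once the
    validation loss has not improved for ``patience`` epochs (the best
    parameters are restored). Divergence (non-finite loss) raises.
    """
    if len(X) != len(y):
        raise ValueError("inputs and labels differ in length")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params, lr=cfg.learning_rate)
    history: list[float] = []
    best_val, best_params, stall = np.inf, None, 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(X))
        losses = []
        for s in range(0, len(X), cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            logits, cache = model.forward(X[idx], train=True, rng=rng)
            loss, dlogits = bce_from_logits(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss!r}; "
                    "reduce the learning rate or check the inputs"
                )
            grads = model.backward(dlogits, cache)
            opt.step(model.params, grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if X_val is not None and cfg.patience is not None:
            pv = np.clip(model.predict(X_val), 1e-12, 1 - 1e-12)
            vl, _ = bce_from_logits(np.log(pv) - np.log1p(-pv), y_val)
            if vl < best_val - 1e-6:
                best_val, stall = vl, 0
                best_params = {k: v.copy() for k, v in model.params.items()}
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
    if best_params is not None:
        model.params = best_params
    return history
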