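"""Downstream cell-type classification on corrected latent representations.

A multilayer perceptron (hidden layers with batch normalization and ReLU,
softmax cross-entropy output, Adam) is trained on z-score-normalized
latent features under leave-one-batch-out cross-validation: each batch in
turn is the test fold while the others train. Test folds are normalized
with training-fold statistics only. Cells of a type absent from the
training fold are counted as misclassified, which keeps accuracies
conservative and deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MLPConfig", "MLPClassifier", "zscore_features", "lobo_cv"]

_BN_EPS = 1e-5


@dataclass
class MLPConfig:
    hidden_dims: tuple[int, ...] = (800, 800)
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 0.001
    seed: int = 0


def zscore_features(train: np.ndarray, test: np.ndarray | None = None):
    """Per-feature standardization with statistics from the training fold.

    Zero-variance features map to 0 (with a warning). Returns the
    normalized training matrix, or ``(train_n, test_n)`` when a test fold
    is supplied — the test fold uses the training mean and SD.
    """
    train = np.asarray(train, dtype=np.float64)
    if train.shape[0] < 2:
        raise ValueError("need at least 2 cells to standardize")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance features set to 0")
    sd_safe = np.where(dead, 1.0, sd)
    train_n = (train - mean) / sd_safe
    train_n[:, dead] = 0.0
    if test is None:
        return train_n
    test_n = (np.asarray(test, dtype=np.float64) - mean) / sd_safe
    test_n[:, dead] = 0.0
    return train_n, test_n


class MLPClassifier:
    """Minimal MLP: [linear -> batchnorm -> ReLU]* -> linear -> softmax."""

    def __init__(self, input_dim: int, n_classes: int, config: MLPConfig):
        self.config = config
        self.n_classes = n_classes
        rng = np.random.default_rng(config.seed)
        dims = [input_dim, *config.hidden_dims]
        self.W, self.gamma, self.beta = [], [], []
        self.run_mean, self.run_var = [], []
        for i in range(len(config.hidden_dims)):
            self.W.append(rng.normal(0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1])))
            self.gamma.append(np.ones(dims[i + 1]))
            self.beta.append(np.zeros(dims[i + 1]))
            self.run_mean.append(np.zeros(dims[i + 1]))
            self.run_var.append(np.ones(dims[i + 1]))
        self.W_out = rng.normal(0, np.sqrt(1.0 / dims[-1]), size=(dims[-1], n_classes))
        self.b_out = np.zeros(n_classes)
        self._rng = rng

    def _forward(self, X, train: bool):
        h = X
        cache = []
        for i in range(len(self.W)):
            a = h @ self.W[i]
            if train:
                mu = a.mean(axis=0)
                var = a.var(axis=0)
                self.run_mean[i] = 0.9 * self.run_mean[i] + 0.1 * mu
                self.run_var[i] = 0.9 * self.run_var[i] + 0.1 * var
            else:
                mu, var = self.run_mean[i], self.run_var[i]
            inv_sd = 1.0 / np.sqrt(var + _BN_EPS)
            ahat = (a - mu) * inv_sd
            out = self.gamma[i] * ahat + self.beta[i]
            relu = np.maximum(out, 0.0)
            cache.append((h, ahat, inv_sd, out))
            h = relu
        logits = h @ self.W_out + self.b_out
        return logits, h, cache

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPClassifier":
        cfg = self.config
        n = X.shape[0]
        # Adam state
        params = self._param_list()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        t = 0
        for epoch in range(cfg.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                if len(idx) < 2:
                    continue  # batch norm needs > 1 sample
                grads = self._grads(X[idx], y[idx])
                t += 1
                for j, (p, g) in enumerate(zip(params, grads)):
                    m[j] = 0.9 * m[j] + 0.1 * g
                    v[j] = 0.999 * v[j] + 0.001 * g * g
                    mhat = m[j] / (1 - 0.9**t)
                    vhat = v[j] / (1 - 0.999**t)
                    p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + 1e-8)
        return self

    def _param_list(self):
        return [*self.W, *self.gamma, *self.beta, self.W_out, self.b_out]

    def _grads(self, X, y):
        B = X.shape[0]
        logits, h_last, cache = self._forward(X, train=True)
        logits = logits - logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        probs = expl / expl.sum(axis=1, keepdims=True)
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        gW_out = h_last.T @ dlogits
        gb_out = dlogits.sum(axis=0)
        dh = dlogits @ self.W_out.T
        L = len(self.W)
        gW = [None] * L
        ggamma = [None] * L
        gbeta = [None] * L
        for i in reversed(range(L)):
            h_in, ahat, inv_sd, out = cache[i]
            dout = dh * (out > 0)
            ggamma[i] = (dout * ahat).sum(axis=0)
            gbeta[i] = dout.sum(axis=0)
            dahat = dout * self.gamma[i]
            # batch-norm backward
            da = inv_sd / B * (
                B * dahat - dahat.sum(axis=0) - ahat * (dahat * ahat).sum(axis=0)
            )
            gW[i] = h_in.T @ da
            dh = da @ self.W[i].T
        return [*gW, *ggamma, *gbeta, gW_out, gb_out]

    def predict(self, X: np.ndarray) -> np.ndarray:
        logits, _, _ = self._forward(np.asarray(X, dtype=np.float64), train=False)
        return logits.argmax(axis=1)


def lobo_cv(
    latents: np.ndarray,
    type_labels: np.ndarray,
    batch_labels: np.ndarray,
    config: MLPConfig | None = None,
) -> pd.DataFrame:
    """Leave-one-batch-out cross-validated cell-type accuracy.

    Returns one row per left-out batch with columns
    ``(fold, left_out_batch, n_test, accuracy)``; the per-fold class set
    is fixed to the global cell-type catalogue so test cells of unseen
    types score as errors. Aggregate with ``df["accuracy"].mean()``.
    """
    config = config or MLPConfig()
    latents = np.asarray(latents, dtype=np.float64)
    type_labels = np.asarray(type_labels, dtype=object).astype(str)
    batch_labels = np.asarray(batch_labels, dtype=object).astype(str)
    classes = np.unique(type_labels)
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.asarray([class_index[c] for c in type_labels])
    batches = list(pd.unique(batch_labels))
    if len(batches) < 2:
        raise ValueError("leave-one-batch-out needs at least 2 batches")
    rows = []
    for fold, b in enumerate(batches):
        test = batch_labels == b
        train = ~test
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"training fold without batch {b!r} has fewer than 2 types")
        Xtr, Xte = zscore_features(latents[train], latents[test])
        clf = MLPClassifier(latents.shape[1], len(classes), config)
        clf.fit(Xtr, y[train])
        pred = clf.predict(Xte)
        acc = float((pred == y[test]).mean())
        rows.append(
            {"fold": fold, "left_out_batch": b, "n_test": int(test.sum()), "accuracy": acc}
        )
    return pd.DataFrame(rows)
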