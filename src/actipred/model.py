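"""Logistic regression trained by plain stochastic gradient descent.

The classifier is deliberately minimal: readmission probability
``p = σ(w·x + b)`` with the logistic function ``σ``, fitted by
per-example SGD updates

    w_i ← w_i − α (p − y) x_i ,    b ← b − α (p − y)

(the gradient of the log-loss), shuffling the examples each epoch and
stopping when the epoch-mean log-loss improvement falls below a
tolerance. Features are standardized (z-scored) with statistics taken
from the training data only; the standardization travels with the model
so prediction accepts raw feature vectors.

Cross-validation is blocked k-fold (folds built by
:mod:`actipred.windows`); the final model averages the k fold models'
weights and biases element-wise, with pooled standardization.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "LogisticModel",
    "CVResult",
    "sigmoid",
    "sgd_step",
    "train",
    "predict",
    "predict_proba",
    "cross_validate",
]

SCHEMA_VERSION = 1


def sigmoid(x):
    """Numerically stable logistic function 1 / (1 + e^{−x})."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return float(out) if out.ndim == 0 else out


def _log_loss_term(z: float, y: float) -> float:
    # -log p(y | z) = log(1 + e^z) - y z, computed without overflow
    return float(np.logaddexp(0.0, z) - y * z)


@dataclass
class LogisticModel:
    """Weights, bias, decision threshold, and training metadata."""

    weights: np.ndarray
    bias: float
    learning_rate: float = 0.01
    n_epochs: int = 200
    threshold: float = 0.5
    feature_names: list[str] | None = None
    standardize_mean: np.ndarray | None = None
    standardize_sd: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not np.all(np.isfinite(self.weights)) or not math.isfinite(self.bias):
            raise ValueError("model parameters must be finite")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")

    def standardized(self, X: np.ndarray) -> np.ndarray:
        if self.standardize_mean is None:
            return X
        return (X - self.standardize_mean) / self.standardize_sd

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "learning_rate": self.learning_rate,
            "n_epochs": self.n_epochs,
            "threshold": self.threshold,
            "feature_names": self.feature_names,
            "standardize_mean": (
                None
                if self.standardize_mean is None
                else self.standardize_mean.tolist()
            ),
            "standardize_sd": (
                None if self.standardize_sd is None else self.standardize_sd.tolist()
            ),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LogisticModel":
        p = json.loads(Path(path).read_text())
        if p.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema: {p.get('schema_version')}")
        return cls(
            weights=np.asarray(p["weights"], dtype=np.float64),
            bias=float(p["bias"]),
            learning_rate=p["learning_rate"],
            n_epochs=p["n_epochs"],
            threshold=p["threshold"],
            feature_names=p["feature_names"],
            standardize_mean=(
                None
                if p["standardize_mean"] is None
                else np.asarray(p["standardize_mean"], dtype=np.float64)
            ),
            standardize_sd=(
                None
                if p["standardize_sd"] is None
                else np.asarray(p["standardize_sd"], dtype=np.float64)
            ),
            seed=p["seed"],
        )


def sgd_step(model: LogisticModel, x: Sequence[float], y: int) -> LogisticModel:
    """One SGD update on a single (already standardized) example.

    Returns a new model; the input model is unchanged.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape != model.weights.shape:
        raise ValueError("feature dimension mismatch")
    if np.isnan(x).any():
        raise ValueError("NaN in feature vector")
    z = float(model.weights @ x) + model.bias
    p = sigmoid(z)
    g = p - float(y)
    return dataclasses.replace(
        model,
        weights=model.weights - model.learning_rate * g * x,
        bias=model.bias - model.learning_rate * g,
    )


def _fit_standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant features pass through
    return mean, sd


def train(
    X: np.ndarray,
    y: np.ndarray,
    learning_rate: float = 0.01,
    n_epochs: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    threshold: float = 0.5,
    standardize: bool = True,
    class_weight: dict[int, float] | None = None,
    feature_names: list[str] | None = None,
) -> LogisticModel:
    """Fit by shuffled per-example SGD with early stopping.

    Weights start from seeded small random values; examples are
    reshuffled every epoch; training stops after ``n_epochs`` or when
    the epoch-mean log-loss improves by less than ``tol``.
    ``class_weight`` optionally scales each example's gradient by its
    class weight (off by default).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, d) aligned with y")
    if np.isnan(X).any():
        raise ValueError("NaN in feature matrix")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set must contain both classes")

    mean = sd = None
    if standardize:
        mean, sd = _fit_standardizer(X)
        X = (X - mean) / sd

    rng = np.random.default_rng(seed)
    n, d = X.shape
    w = rng.normal(0.0, 0.01, size=d)
    b = float(rng.normal(0.0, 0.01))
    cw = {0: 1.0, 1: 1.0}
    if class_weight:
        cw.update({int(k): float(v) for k, v in class_weight.items()})

    prev_loss = math.inf
    for _ in range(n_epochs):
        order = rng.permutation(n)
        total = 0.0
        for i in order:
            xi = X[i]
            yi = y[i]
            z = float(w @ xi) + b
            p = sigmoid(z)
            g = (p - yi) * cw[int(yi)] * learning_rate
            if g != 0.0:
                w -= g * xi
                b -= g
            total += _log_loss_term(z, yi) * cw[int(yi)]
        loss = total / n
        if prev_loss - loss < tol:
            break
        prev_loss = loss

    return LogisticModel(
        weights=w,
        bias=b,
        learning_rate=learning_rate,
        n_epochs=n_epochs,
        threshold=threshold,
        feature_names=feature_names,
        standardize_mean=mean,
        standardize_sd=sd,
        seed=seed,
    )


def predict_proba(model: LogisticModel, X: np.ndarray) -> np.ndarray:
    """Readmission probabilities for raw (unstandardized) feature rows."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.weights.shape[0]:
        raise ValueError("feature dimension mismatch")
    Z = model.standardized(X) @ model.weights + model.bias
    return sigmoid(Z)


def predict(model: LogisticModel, x: Sequence[float]) -> tuple[float, bool]:
    """(probability, predicted readmission) for one window.

    A readmission is declared when probability ≥ threshold (inclusive).
    """
    p = float(predict_proba(model, np.asarray(x, dtype=np.float64))[0])
    return p, p >= model.threshold


@dataclass
class CVResult:
    fold_models: list[LogisticModel]
    fold_log_loss: list[float]
    fold_accuracy: list[float]
    averaged_model: LogisticModel
    oof_proba: np.ndarray  # out-of-fold probability per window (NaN if unused)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def mean_log_loss(self) -> float:
        return float(np.mean(self.fold_log_loss))


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    folds: Sequence[np.ndarray],
    learning_rate: float = 0.01,
    n_epochs: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    threshold: float = 0.5,
    class_weight: dict[int, float] | None = None,
    feature_names: list[str] | None = None,
) -> CVResult:
    """Blocked k-fold training: per fold, standardize on the training
    part, train, and score the held-out fold (log-loss and thresholded
    classification accuracy).

    The averaged model takes the element-wise mean of the fold models'
    weights and biases, with standardization pooled over all rows; each
    row also receives an out-of-fold probability from the model that
    held it out.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    k = len(folds)
    if k < 2:
        raise ValueError("need at least 2 folds")
    for f in folds:
        if len(f) == 0:
            raise ValueError("empty fold")

    all_idx = np.concatenate(folds)
    fold_models: list[LogisticModel] = []
    fold_ll: list[float] = []
    fold_acc: list[float] = []
    oof = np.full(len(X), np.nan)

    for j, test_idx in enumerate(folds):
        train_idx = np.concatenate([f for i, f in enumerate(folds) if i != j])
        m = train(
            X[train_idx],
            y[train_idx],
            learning_rate=learning_rate,
            n_epochs=n_epochs,
            tol=tol,
            seed=seed,
            threshold=threshold,
            class_weight=class_weight,
            feature_names=feature_names,
        )
        p = predict_proba(m, X[test_idx])
        oof[test_idx] = p
        eps = 1e-12
        ll = float(
            -np.mean(
                y[test_idx] * np.log(np.clip(p, eps, 1.0))
                + (1 - y[test_idx]) * np.log(np.clip(1 - p, eps, 1.0))
            )
        )
        acc = float(np.mean((p >= threshold) == (y[test_idx] == 1)))
        fold_models.append(m)
        fold_ll.append(ll)
        fold_acc.append(acc)

    pooled_mean, pooled_sd = _fit_standardizer(X[all_idx])
    averaged = LogisticModel(
        weights=np.mean([m.weights for m in fold_models], axis=0),
        bias=float(np.mean([m.bias for m in fold_models])),
        learning_rate=learning_rate,
        n_epochs=n_epochs,
        threshold=threshold,
        feature_names=feature_names,
        standardize_mean=pooled_mean,
        standardize_sd=pooled_sd,
        seed=seed,
    )
    return CVResult(fold_models, fold_ll, fold_acc, averaged, oof)
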