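"""One-hidden-layer feedforward classifier for the source indicator.

Architecture: input width Xi (the selected alpha components), one hidden
layer of U neurons (default 100) with ReLU activation, and O = 5 linear
output units scoring the classes (S, E, D, F, S+E).  The computation per
sample is

    S_u = sum_xi w_u,xi alpha_xi + beta_xi        (hidden pre-activation)
    g_u = max(S_u, 0)                             (ReLU)
    y_o = sum_u w~_u,o g_u + beta_u               (class scores)

with predicted class argmax_o y_o (ties resolved to the lowest index).  The
total connection count is Xi*U + U*O.

Training minimizes softmax cross-entropy by mini-batch gradient descent with
momentum; inputs are z-scored with statistics fitted on the training data
only (the alpha components differ by orders of magnitude).  All randomness —
initialization, batch shuffling, fold assignment — flows from one seed, so
identical inputs reproduce identical reports.

Validation is stratified k-fold (default k = 5); accuracy is
Acc = 100 * T_predict / T_samples and the 5x5 confusion matrix is
row-normalized to percent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .dielectric import InvalidInputError

__all__ = [
    "NetworkParams",
    "TrainConfig",
    "EvalReport",
    "init_network",
    "forward_pass",
    "train",
    "kfold_validate",
    "confusion_matrix",
    "save_model",
    "load_model",
    "CLASS_NAMES",
]

CLASS_NAMES = {1: "S", 2: "E", 3: "D", 4: "F", 5: "S+E"}


@dataclass
class NetworkParams:
    """Weights, biases and input scaler of the one-hidden-layer network."""

    W1: np.ndarray  # (U, Xi) input->hidden
    b1: np.ndarray  # (U,)
    W2: np.ndarray  # (O, U) hidden->output
    b2: np.ndarray  # (O,)
    seed: int | None = None
    scaler_mean: np.ndarray | None = None
    scaler_std: np.ndarray | None = None

    @property
    def input_width(self) -> int:
        return self.W1.shape[1]

    @property
    def hidden_width(self) -> int:
        return self.W1.shape[0]

    @property
    def output_width(self) -> int:
        return self.W2.shape[0]

    @property
    def connection_count(self) -> int:
        """Xi*U + U*O weight connections."""
        return self.input_width * self.hidden_width + self.hidden_width * self.output_width


def init_network(xi: int, u: int, o: int, seed: int | None = None) -> NetworkParams:
    """Seeded He-scaled normal initialization; biases start at zero."""
    if xi < 1 or u < 1 or o < 1:
        raise InvalidInputError("network widths must be >= 1")
    rng = np.random.default_rng(seed)
    W1 = rng.standard_normal((u, xi)) * np.sqrt(2.0 / xi)
    W2 = rng.standard_normal((o, u)) * np.sqrt(2.0 / u)
    return NetworkParams(W1, np.zeros(u), W2, np.zeros(o), seed=seed)


def _scale(net: NetworkParams, X: np.ndarray) -> np.ndarray:
    if net.scaler_mean is None:
        return X
    return (X - net.scaler_mean) / net.scaler_std


def _forward_batch(net: NetworkParams, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hidden activations and class scores for an (n, Xi) batch (already scaled)."""
    H = np.maximum(X @ net.W1.T + net.b1, 0.0)
    Y = H @ net.W2.T + net.b2
    return H, Y


def forward_pass(
    net: NetworkParams, alpha: Sequence[float], softmax: bool = False
) -> tuple[np.ndarray, int]:
    """Class scores y_o and predicted class k (1-based) for one feature tuple.

    Ties in the argmax resolve to the lowest class index.  With
    ``softmax=True`` the scores are returned as normalized probabilities.
    """
    a = np.asarray(alpha, dtype=float)
    if a.shape != (net.input_width,):
        raise InvalidInputError(
            f"feature width {a.shape} does not match network input {net.input_width}"
        )
    _, y = _forward_batch(net, _scale(net, a[None, :]))
    y = y[0]
    k = int(np.argmax(y)) + 1  # np.argmax returns the first (lowest) maximizer
    if softmax:
        e = np.exp(y - y.max())
        y = e / e.sum()
    return y, k


def predict(net: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Predicted classes (1-based) for an (n, Xi) matrix."""
    _, Y = _forward_batch(net, _scale(net, np.asarray(X, dtype=float)))
    return np.argmax(Y, axis=1) + 1


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (toolbox-style defaults, all overridable)."""

    hidden_width: int = 100
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 0.05
    momentum: float = 0.9
    standardize: bool = True
    n_classes: int = 5


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig = TrainConfig(),
    seed: int | None = None,
    sample_weight: np.ndarray | None = None,
) -> NetworkParams:
    """Fit the network by mini-batch momentum SGD on softmax cross-entropy.

    ``y`` holds 1-based class labels; ``sample_weight`` (e.g. balancing class
    weights) scales each sample's loss contribution.  Deterministic for a
    fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) == 0:
        raise InvalidInputError("empty training set")
    if X.ndim != 2 or len(X) != len(y):
        raise InvalidInputError("X must be (n, Xi) matching y")
    if np.any(y < 1) or np.any(y > config.n_classes):
        raise InvalidInputError(f"labels must lie in 1..{config.n_classes}")
    w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)

    net = init_network(X.shape[1], config.hidden_width, config.n_classes, seed)
    if config.standardize:
        net.scaler_mean = X.mean(axis=0)
        std = X.std(axis=0)
        net.scaler_std = np.where(std > 0, std, 1.0)
    Xs = _scale(net, X)
    T = np.zeros((len(y), config.n_classes))
    T[np.arange(len(y)), y - 1] = 1.0

    rng = np.random.default_rng(None if seed is None else seed + 1)
    vW1 = np.zeros_like(net.W1); vb1 = np.zeros_like(net.b1)
    vW2 = np.zeros_like(net.W2); vb2 = np.zeros_like(net.b2)
    n = len(y)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, tb, wb = Xs[idx], T[idx], w[idx]
            H, Y = _forward_batch(net, xb)
            Ys = Y - Y.max(axis=1, keepdims=True)
            P = np.exp(Ys)
            P /= P.sum(axis=1, keepdims=True)
            if not np.all(np.isfinite(P)):
                raise RuntimeError("NaN in softmax during training; "
                                   "check feature scaling / learning rate")
            G = (P - tb) * wb[:, None] / wb.sum()
            gW2 = G.T @ H
            gb2 = G.sum(axis=0)
            GH = (G @ net.W2) * (H > 0)
            gW1 = GH.T @ xb
            gb1 = GH.sum(axis=0)
            lr, mom = config.learning_rate, config.momentum
            vW2 = mom * vW2 - lr * gW2; net.W2 += vW2
            vb2 = mom * vb2 - lr * gb2; net.b2 += vb2
            vW1 = mom * vW1 - lr * gW1; net.W1 += vW1
            vb1 = mom * vb1 - lr * gb1; net.b1 += vb1
    return net


def confusion_matrix(
    true_labels: Sequence[int],
    predicted_labels: Sequence[int],
    n_classes: int = 5,
) -> tuple[np.ndarray, list[int]]:
    """Row-normalized percent confusion matrix and the list of absent true classes.

    Row i, column j: percent of true-class-(i+1) samples predicted as (j+1).
    Rows of absent classes are NaN (flagged, not zero-filled).
    """
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if len(t) == 0:
        raise InvalidInputError("empty label lists")
    if len(t) != len(p):
        raise InvalidInputError("label lists must have equal length")
    counts = np.zeros((n_classes, n_classes))
    for ti, pi in zip(t, p):
        counts[ti - 1, pi - 1] += 1
    rowsum = counts.sum(axis=1)
    absent = [i + 1 for i in range(n_classes) if rowsum[i] == 0]
    cm = np.full((n_classes, n_classes), np.nan)
    ok = rowsum > 0
    cm[ok] = 100.0 * counts[ok] / rowsum[ok, None]
    return cm, absent


@dataclass
class EvalReport:
    """Cross-validated evaluation: overall accuracy, folds, confusion matrix."""

    accuracy: float  # Acc [%] over all folds
    fold_accuracies: list[float]
    confusion: np.ndarray  # (5, 5) row-normalized [%], NaN rows for absent classes
    n_samples: int
    t_predict: int  # number of correct predictions
    seed: int | None
    absent_classes: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy,
            "fold_accuracies_pct": self.fold_accuracies,
            "confusion_matrix_pct": [
                [None if np.isnan(v) else v for v in row] for row in self.confusion
            ],
            "n_samples": self.n_samples,
            "t_predict": self.t_predict,
            "seed": self.seed,
            "absent_classes": self.absent_classes,
            "class_names": [CLASS_NAMES[k] for k in sorted(CLASS_NAMES)],
        }


def kfold_validate(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int | None = None,
    config: TrainConfig = TrainConfig(),
    sample_weight: np.ndarray | None = None,
) -> EvalReport:
    """Stratified k-fold cross-validation with Acc = 100 * T_predict / T_samples."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise InvalidInputError("k must be >= 2")
    if len(X) < k:
        raise InvalidInputError("dataset smaller than the number of folds")
    present = sorted(set(y.tolist()))
    import warnings
    if set(range(1, config.n_classes + 1)) - set(present):
        missing = sorted(set(range(1, config.n_classes + 1)) - set(present))
        warnings.warn(f"classes {missing} absent from the dataset; "
                      f"reporting on {len(present)} classes", stacklevel=2)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    true_all, pred_all, fold_accs = [], [], []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        sw = None if sample_weight is None else np.asarray(sample_weight)[tr]
        net = train(X[tr], y[tr], config,
                    seed=None if seed is None else seed + fold, sample_weight=sw)
        yp = predict(net, X[te])
        fold_accs.append(100.0 * float(np.mean(yp == y[te])))
        true_all.extend(y[te].tolist())
        pred_all.extend(yp.tolist())
    t_predict = int(np.sum(np.array(true_all) == np.array(pred_all)))
    acc = 100.0 * t_predict / len(true_all)
    cm, absent = confusion_matrix(true_all, pred_all, config.n_classes)
    return EvalReport(
        accuracy=acc, fold_accuracies=fold_accs, confusion=cm,
        n_samples=len(true_all), t_predict=t_predict, seed=seed,
        absent_classes=absent,
    )


# --------------------------------------------------------------------------
# Model persistence (JSON)
# --------------------------------------------------------------------------

def save_model(net: NetworkParams, path: str | Path, meta: dict | None = None) -> None:
    doc = {
        "format_version": 1,
        "widths": [net.input_width, net.hidden_width, net.output_width],
        "W1": net.W1.tolist(), "b1": net.b1.tolist(),
        "W2": net.W2.tolist(), "b2": net.b2.tolist(),
        "seed": net.seed,
        "scaler_mean": None if net.scaler_mean is None else net.scaler_mean.tolist(),
        "scaler_std": None if net.scaler_std is None else net.scaler_std.tolist(),
        "meta": meta or {},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str | Path) -> tuple[NetworkParams, dict]:
    with open(path) as fh:
        doc = json.load(fh)
    net = NetworkParams(
        W1=np.array(doc["W1"]), b1=np.array(doc["b1"]),
        W2=np.array(doc["W2"]), b2=np.array(doc["b2"]),
        seed=doc.get("seed"),
        scaler_mean=None if doc["scaler_mean"] is None else np.array(doc["scaler_mean"]),
        scaler_std=None if doc["scaler_std"] is None else np.array(doc["scaler_std"]),
    )
    return net, doc.get("meta", {})
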