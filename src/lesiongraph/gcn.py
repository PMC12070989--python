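"""From-scratch two-layer graph convolutional classifier (numpy only).

Propagation uses the symmetrically normalized adjacency with self-loops,
A_hat = D^{-1/2} (A + I) D^{-1/2}, where A holds the (non-binarized) edge
weights.  Two ReLU graph-convolution layers are followed by global mean
pooling and a dense softmax head:

    H1 = relu(A_hat X W1)
    H2 = relu(A_hat H1 W2)
    h  = mean_v H2[v]
    logits = h @ Wc + bc

Gradients are derived analytically; training supports mini-batch Adam or SGD
with early stopping on validation loss and best-epoch parameter restoration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ShapeError, TrainingError
from .graphs import LesionGraph

__all__ = [
    "GCNParams",
    "TrainConfig",
    "TrainHistory",
    "init_params",
    "normalized_adjacency",
    "gcn_forward",
    "cross_entropy",
    "train",
    "evaluate",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

_PROB_FLOOR = 1e-12


@dataclass
class GCNParams:
    """Learnable tensors: two conv weight matrices plus the dense head."""

    W1: np.ndarray  # (F, F')
    W2: np.ndarray  # (F', F'')
    Wc: np.ndarray  # (F'', C)
    bc: np.ndarray  # (C,)

    @property
    def n_classes(self) -> int:
        return self.Wc.shape[1]

    def copy(self) -> "GCNParams":
        return GCNParams(self.W1.copy(), self.W2.copy(), self.Wc.copy(), self.bc.copy())

    def tensors(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1, "W2": self.W2, "Wc": self.Wc, "bc": self.bc}

    def validate(self) -> None:
        for name, t in self.tensors().items():
            if not np.isfinite(t).all():
                raise TrainingError(f"parameter {name} contains non-finite entries")


@dataclass(frozen=True)
class TrainConfig:
    hidden_dim: int = 32
    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 8
    patience: int = 3
    rng_seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self):
        if self.hidden_dim <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ShapeError("hidden_dim, epochs and batch_size must be positive")
        if self.patience < 1:
            raise ShapeError("patience must be >= 1")
        if self.learning_rate < 0:
            raise ShapeError("learning_rate must be >= 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ShapeError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainHistory:
    """Per-epoch traces; accuracies are fractions in [0, 1], losses mean CE."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    epochs_run: int = 0
    best_epoch: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, self.epochs_run + 1),
                "ATL": self.train_loss,
                "ATA": self.train_acc,
                "AVL": self.val_loss,
                "AVA": self.val_acc,
            }
        )


def init_params(n_features: int, hidden_dim: int, n_classes: int, rng_seed: int = 0) -> GCNParams:
    """Seeded Glorot-uniform initialization; zero classifier bias."""
    rng = np.random.default_rng(rng_seed)

    def glorot(fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    return GCNParams(
        W1=glorot(n_features, hidden_dim),
        W2=glorot(hidden_dim, hidden_dim),
        Wc=glorot(hidden_dim, n_classes),
        bc=np.zeros(n_classes),
    )


def normalized_adjacency(graph: LesionGraph) -> np.ndarray:
    """A_hat = D^{-1/2} (A + I) D^{-1/2} with unit self-loop weights."""
    A = graph.weight_matrix()
    A_tilde = A + np.eye(graph.n_nodes)
    d = A_tilde.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    return A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _forward_cached(params: GCNParams, X: np.ndarray, A_hat: np.ndarray):
    if X.shape[1] != params.W1.shape[0]:
        raise ShapeError(
            f"node feature dim {X.shape[1]} != W1 input dim {params.W1.shape[0]}"
        )
    AX = A_hat @ X
    Z1 = AX @ params.W1
    H1 = np.maximum(Z1, 0.0)
    AH1 = A_hat @ H1
    Z2 = AH1 @ params.W2
    H2 = np.maximum(Z2, 0.0)
    h = H2.mean(axis=0)
    logits = h @ params.Wc + params.bc
    probs = _softmax(logits)
    cache = {"X": X, "A_hat": A_hat, "AX": AX, "Z1": Z1, "H1": H1, "AH1": AH1,
             "Z2": Z2, "H2": H2, "h": h, "probs": probs}
    return logits, probs, cache


def gcn_forward(
    params: GCNParams, graph: LesionGraph, A_hat: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Graph-level (logits, probabilities) for one graph."""
    if A_hat is None:
        A_hat = normalized_adjacency(graph)
    logits, probs, _ = _forward_cached(params, graph.features, A_hat)
    return logits, probs


def cross_entropy(probs: np.ndarray, labels: Sequence[int]) -> float:
    """Mean negative log-probability of the true class (floor 1e-12)."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if probs.shape[0] != labels.shape[0]:
        raise ShapeError("probs and labels disagree in length")
    p_true = np.clip(probs[np.arange(len(labels)), labels], _PROB_FLOOR, 1.0)
    return float(-np.log(p_true).mean())


def _backward(params: GCNParams, cache: dict, label: int) -> dict[str, np.ndarray]:
    """Analytic gradients of the single-graph cross-entropy loss."""
    probs = cache["probs"]
    n = cache["X"].shape[0]
    dlogits = probs.copy()
    dlogits[label] -= 1.0  # d(CE)/d(logits) of softmax-CE
    dWc = np.outer(cache["h"], dlogits)
    dbc = dlogits
    dh = params.Wc @ dlogits
    dH2 = np.repeat(dh[None, :], n, axis=0) / n  # mean-pool backward
    dZ2 = dH2 * (cache["Z2"] > 0)
    dW2 = cache["AH1"].T @ dZ2
    dH1 = cache["A_hat"].T @ (dZ2 @ params.W2.T)
    dZ1 = dH1 * (cache["Z1"] > 0)
    dW1 = cache["AX"].T @ dZ1
    return {"W1": dW1, "W2": dW2, "Wc": dWc, "bc": dbc}


def loss_and_grads(
    params: GCNParams, items: Sequence[tuple[np.ndarray, np.ndarray, int]]
) -> tuple[float, float, dict[str, np.ndarray]]:
    """Batch-averaged (loss, accuracy, gradients) over (X, A_hat, label) items."""
    grads = {k: np.zeros_like(v) for k, v in params.tensors().items()}
    losses = []
    correct = 0
    for X, A_hat, label in items:
        _, probs, cache = _forward_cached(params, X, A_hat)
        losses.append(cross_entropy(probs[None, :], [label]))
        correct += int(int(np.argmax(probs)) == label)
        g = _backward(params, cache, label)
        for k in grads:
            grads[k] += g[k]
    m = len(items)
    for k in grads:
        grads[k] /= m
    return float(np.mean(losses)), correct / m, grads


class _Adam:
    def __init__(self, params: GCNParams, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.tensors().items()}
        self.v = {k: np.zeros_like(v) for k, v in params.tensors().items()}
        self.t = 0

    def step(self, params: GCNParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, tensor in params.tensors().items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / (1 - self.beta1**self.t)
            v_hat = self.v[k] / (1 - self.beta2**self.t)
            tensor -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class _SGD:
    def __init__(self, params: GCNParams, lr: float):
        self.lr = lr

    def step(self, params: GCNParams, grads: dict[str, np.ndarray]) -> None:
        for k, tensor in params.tensors().items():
            tensor -= self.lr * grads[k]


def _prepare(items: Sequence[tuple[LesionGraph, int]]):
    return [(g.features, normalized_adjacency(g), int(y)) for g, y in items]


def evaluate(
    params: GCNParams, items, prepared: bool = False
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """(mean loss, accuracy, predictions, probability matrix) on a graph set."""
    data = items if prepared else _prepare(items)
    probs = np.zeros((len(data), params.n_classes))
    labels = np.zeros(len(data), dtype=int)
    for idx, (X, A_hat, y) in enumerate(data):
        _, p, _ = _forward_cached(params, X, A_hat)
        probs[idx] = p
        labels[idx] = y
    preds = np.argmax(probs, axis=1)
    loss = cross_entropy(probs, labels)
    acc = float((preds == labels).mean())
    return loss, acc, preds, probs


def train(
    train_set: Sequence[tuple[LesionGraph, int]],
    val_set: Sequence[tuple[LesionGraph, int]],
    cfg: TrainConfig,
    init: GCNParams | None = None,
    n_classes: int | None = None,
    baseline_as_best: bool = False,
) -> tuple[GCNParams, TrainHistory]:
    """Mini-batch training with early stopping on validation loss.

    Stops when validation loss fails to improve for ``cfg.patience``
    consecutive epochs and restores the best-validation parameters.  With
    ``baseline_as_best`` the incoming parameters' validation loss is the
    initial incumbent, so the returned model is never worse than ``init``
    (used by fine-tuning).
    """
    if not train_set or not val_set:
        raise TrainingError("train and validation sets must be non-empty")
    labels = sorted({int(y) for _, y in train_set})
    if len(labels) < 2:
        raise TrainingError("training labels must cover at least 2 classes")
    if n_classes is None:
        n_classes = max(max(labels), max(int(y) for _, y in val_set)) + 1
    n_feat = train_set[0][0].features.shape[1]

    params = init.copy() if init is not None else init_params(
        n_feat, cfg.hidden_dim, n_classes, cfg.rng_seed
    )
    opt = _Adam(params, cfg.learning_rate) if cfg.optimizer == "adam" else _SGD(
        params, cfg.learning_rate
    )
    rng = np.random.default_rng(cfg.rng_seed)
    train_data = _prepare(train_set)
    val_data = _prepare(val_set)

    history = TrainHistory()
    best_params = params.copy()
    if baseline_as_best:
        best_val, _, _, _ = evaluate(params, val_data, prepared=True)
        best_epoch = 0
    else:
        best_val, best_epoch = np.inf, 0
    stale = 0
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(train_data))
        batch_losses, batch_accs = [], []
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_data[i] for i in order[start : start + cfg.batch_size]]
            loss, acc, grads = loss_and_grads(params, batch)
            if not np.isfinite(loss):
                history.epochs_run = epoch - 1
                raise TrainingError("training diverged (non-finite loss)", history)
            opt.step(params, grads)
            batch_losses.append(loss)
            batch_accs.append(acc)
        val_loss, val_acc, _, _ = evaluate(params, val_data, prepared=True)
        history.train_loss.append(float(np.mean(batch_losses)))
        history.train_acc.append(float(np.mean(batch_accs)))
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)
        history.epochs_run = epoch
        if val_loss < best_val:
            best_val, best_epoch = val_loss, epoch
            best_params = params.copy()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    history.best_epoch = best_epoch
    return best_params, history


def predict(params: GCNParams, graph: LesionGraph) -> int:
    """argmax class; ties break toward the lowest class index."""
    _, probs = gcn_forward(params, graph)
    return int(np.argmax(probs))


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(params: GCNParams, path, cfg: TrainConfig | None = None) -> None:
    doc = {
        "format_version": 1,
        "shapes": {k: list(v.shape) for k, v in params.tensors().items()},
        "tensors": {k: v.tolist() for k, v in params.tensors().items()},
    }
    if cfg is not None:
        doc["config"] = {
            "hidden_dim": cfg.hidden_dim,
            "learning_rate": cfg.learning_rate,
            "epochs": cfg.epochs,
            "batch_size": cfg.batch_size,
            "patience": cfg.patience,
            "rng_seed": cfg.rng_seed,
            "optimizer": cfg.optimizer,
        }
    Path(path).write_text(json.dumps(doc))


def load_checkpoint(path) -> GCNParams:
    doc = json.loads(Path(path).read_text())
    tensors = {k: np.asarray(v, dtype=float) for k, v in doc["tensors"].items()}
    params = GCNParams(W1=tensors["W1"], W2=tensors["W2"], Wc=tensors["Wc"], bc=tensors["bc"])
    params.validate()
    return params
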