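"""Stratified K-fold cross-validation with exhaustive grid search and a
two-phase (initial training + fine-tuning) protocol.

Each fold: grid search on the training portion selects (hidden_dim,
learning_rate, epochs) by inner macro F1, a final model trains on the fold's
training data with early stopping, and the held-out fold is scored.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import StratificationError
from .gcn import GCNParams, TrainConfig, TrainHistory, evaluate, train
from .graphs import LesionGraph
from .metrics import classification_report

__all__ = [
    "FoldSplit",
    "HyperGrid",
    "CVReport",
    "kfold_split",
    "stratified_holdout",
    "grid_search",
    "run_cv",
    "fine_tune",
    "standardize_graphs",
]


@dataclass(frozen=True)
class FoldSplit:
    """Fold id per item; folds partition {0..n-1} with sizes differing <= 1."""

    K: int
    assignments: np.ndarray

    def test_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignments == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignments != fold)[0]


@dataclass(frozen=True)
class HyperGrid:
    """Hyperparameter grid searched exhaustively (cartesian product)."""

    hidden_dims: tuple[int, ...] = (32, 64)
    learning_rates: tuple[float, ...] = (0.001, 0.01)
    epoch_options: tuple[int, ...] = (10, 20)

    def __post_init__(self):
        if not (self.hidden_dims and self.learning_rates and self.epoch_options):
            raise StratificationError("grid lists must be non-empty")

    def combinations(self) -> list[tuple[int, float, int]]:
        return list(
            itertools.product(self.hidden_dims, self.learning_rates, self.epoch_options)
        )

    def __len__(self) -> int:
        return len(self.combinations())


def kfold_split(labels: Sequence, K: int, rng_seed: int) -> FoldSplit:
    """Seeded stratified K-fold assignment.

    Items of each class are shuffled and dealt cyclically across folds,
    continuing the deal from class to class so that both total fold sizes and
    per-class counts per fold differ by at most one.
    """
    labels = np.asarray(labels)
    if K < 2:
        raise StratificationError("K must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    short = classes[counts < K]
    if short.size:
        raise StratificationError(
            f"classes {short.tolist()} have fewer than K={K} items"
        )
    rng = np.random.default_rng(rng_seed)
    assignments = np.full(len(labels), -1, dtype=int)
    start = 0
    for cls in classes:
        idx = np.nonzero(labels == cls)[0]
        idx = rng.permutation(idx)
        for t, item in enumerate(idx):
            assignments[item] = (t + start) % K
        start = (start + len(idx)) % K
    return FoldSplit(K=K, assignments=assignments)


def stratified_holdout(
    labels: Sequence, fraction: float, rng_seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class split into (train_idx, holdout_idx); every class appears in both."""
    labels = np.asarray(labels)
    if not 0 < fraction < 1:
        raise StratificationError("holdout fraction must be in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    train_idx, hold_idx = [], []
    for cls in np.unique(labels):
        idx = rng.permutation(np.nonzero(labels == cls)[0])
        if len(idx) < 2:
            raise StratificationError(
                f"class {cls!r} has {len(idx)} item(s); needs >= 2 for a holdout"
            )
        n_hold = min(max(1, int(round(fraction * len(idx)))), len(idx) - 1)
        hold_idx.extend(idx[:n_hold])
        train_idx.extend(idx[n_hold:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(hold_idx))


def standardize_graphs(
    train_graphs: Sequence[LesionGraph], apply_to: Sequence[Sequence[LesionGraph]]
) -> list[list[LesionGraph]]:
    """Z-score node features using statistics pooled over the training graphs.

    Keeps the GCN input well-scaled (raw areas otherwise dominate); the
    transform is fit on training data only and applied to every listed set.
    """
    stacked = np.vstack([g.features for g in train_graphs])
    mu = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    sd[sd == 0] = 1.0
    out = []
    for group in apply_to:
        out.append(
            [
                LesionGraph(
                    node_ids=list(g.node_ids),
                    features=(g.features - mu) / sd,
                    edges=list(g.edges),
                    class_label=g.class_label,
                    provenance=dict(g.provenance),
                )
                for g in group
            ]
        )
    return out


def grid_search(
    train_items: Sequence[tuple[LesionGraph, int]],
    grid: HyperGrid,
    inner_val_fraction: float,
    base_cfg: TrainConfig,
    rng_seed: int,
) -> tuple[dict, pd.DataFrame]:
    """Evaluate every grid combination on a stratified inner split.

    Returns the combination maximizing inner macro F1 (ties go to the first in
    lexicographic grid order) plus the full score table.
    """
    labels = [y for _, y in train_items]
    tr_idx, val_idx = stratified_holdout(labels, inner_val_fraction, rng_seed)
    inner_train = [train_items[i] for i in tr_idx]
    inner_val = [train_items[i] for i in val_idx]
    n_classes = int(max(labels)) + 1
    records = []
    best_score, best_combo = -np.inf, None
    for h, lr, e in grid.combinations():
        cfg = replace(
            base_cfg, hidden_dim=h, learning_rate=lr, epochs=e, rng_seed=rng_seed
        )
        params, _ = train(inner_train, inner_val, cfg, n_classes=n_classes)
        _, _, preds, probs = evaluate(params, inner_val)
        report = classification_report(
            [y for _, y in inner_val], preds, probs, n_classes=n_classes
        )
        records.append(
            {"hidden_dim": h, "learning_rate": lr, "epochs": e, "macro_f1": report.macro_f1}
        )
        if report.macro_f1 > best_score:
            best_score = report.macro_f1
            best_combo = {"hidden_dim": h, "learning_rate": lr, "epochs": e}
    return best_combo, pd.DataFrame.from_records(records)


@dataclass
class CVReport:
    """Per-fold chosen hyperparameters and metrics plus aggregated means."""

    K: int
    folds: list[dict] = field(default_factory=list)
    mean_macro_f1: float = 0.0
    mean_accuracy: float = 0.0
    mean_macro_accuracy: float = 0.0

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "folds": [
                {
                    "fold": f["fold"],
                    "chosen": f["chosen"],
                    "metrics": f["metrics"].to_dict(),
                }
                for f in self.folds
            ],
            "mean_macro_f1": self.mean_macro_f1,
            "mean_accuracy": self.mean_accuracy,
            "mean_macro_accuracy": self.mean_macro_accuracy,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def run_cv(
    items: Sequence[tuple[LesionGraph, int]],
    K: int,
    grid: HyperGrid,
    base_cfg: TrainConfig,
    rng_seed: int,
    final_epochs: int = 100,
    inner_val_fraction: float = 0.2,
    standardize: bool = True,
) -> CVReport:
    """Full cross-validation: per-fold grid search, final training, held-out scoring.

    Grid-search trials run for their gridded epoch budgets; the final per-fold
    model trains with the selected hidden_dim/learning rate for up to
    ``final_epochs`` epochs under early stopping.
    """
    labels = [y for _, y in items]
    split = kfold_split(labels, K, rng_seed)
    n_classes = int(max(labels)) + 1
    report = CVReport(K=K)
    for fold in range(K):
        tr_idx = split.train_indices(fold)
        te_idx = split.test_indices(fold)
        train_items = [items[i] for i in tr_idx]
        test_items = [items[i] for i in te_idx]
        if standardize:
            std_sets = standardize_graphs(
                [g for g, _ in train_items],
                [[g for g, _ in train_items], [g for g, _ in test_items]],
            )
            train_items = [(g, y) for g, (_, y) in zip(std_sets[0], train_items)]
            test_items = [(g, y) for g, (_, y) in zip(std_sets[1], test_items)]
        fold_seed = int(
            np.random.SeedSequence((int(rng_seed), fold)).generate_state(1)[0] % (2**31)
        )
        chosen, _ = grid_search(train_items, grid, inner_val_fraction, base_cfg, fold_seed)
        final_cfg = replace(
            base_cfg,
            hidden_dim=chosen["hidden_dim"],
            learning_rate=chosen["learning_rate"],
            epochs=final_epochs,
            rng_seed=fold_seed,
        )
        inner_tr, inner_val = stratified_holdout(
            [y for _, y in train_items], inner_val_fraction, fold_seed
        )
        params, _ = train(
            [train_items[i] for i in inner_tr],
            [train_items[i] for i in inner_val],
            final_cfg,
            n_classes=n_classes,
        )
        _, _, preds, probs = evaluate(params, test_items)
        fold_report = classification_report(
            [y for _, y in test_items], preds, probs, n_classes=n_classes
        )
        report.folds.append({"fold": fold, "chosen": chosen, "metrics": fold_report})
    report.mean_macro_f1 = float(np.mean([f["metrics"].macro_f1 for f in report.folds]))
    report.mean_accuracy = float(np.mean([f["metrics"].accuracy for f in report.folds]))
    report.mean_macro_accuracy = float(
        np.mean([f["metrics"].macro_accuracy for f in report.folds])
    )
    return report


def fine_tune(
    params: GCNParams,
    train_items: Sequence[tuple[LesionGraph, int]],
    val_items: Sequence[tuple[LesionGraph, int]],
    cfg: TrainConfig,
) -> tuple[GCNParams, TrainHistory]:
    """Continue training at a (typically lower) learning rate with patience-based
    early stopping; the incoming parameters seed the incumbent best, so the
    returned validation loss never exceeds the pre-fine-tune one."""
    return train(
        train_items,
        val_items,
        cfg,
        init=params,
        n_classes=params.n_classes,
        baseline_as_best=True,
    )
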