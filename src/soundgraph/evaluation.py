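"""Scoring: accuracy, predefined-fold cross-validation and holdout splits.

Two evaluation protocols mirror the two benchmark settings: ten predefined
folds scored by leave-one-fold-out cross-validation (the urban-sound
convention, reported as mean ± std across folds), and a stratified 80/20
train/test holdout (the soundscape-monitoring convention, reported as a
single test accuracy).

The k-NN graph is a function of features only, so it is built once over all
nodes and reused across folds; per fold only the supervision mask changes.
The reported std is the population standard deviation across folds
(ddof = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import knn_edges, symmetrize
from .io import EmbeddingTable
from .models import ModelSpec, build_model, count_parameters
from .training import TrainConfig, predict, train


@dataclass
class EvalResult:
    per_fold_accuracy: list[float]
    mean: float
    std: float
    n_test_nodes: list[int]
    config: dict = field(default_factory=dict)

    def __str__(self) -> str:  # "0.77 ± 0.04" reporting convention
        return f"{self.mean:.2f} ± {self.std:.2f}"


def accuracy(
    predictions: np.ndarray, truth: np.ndarray, mask: np.ndarray
) -> float:
    """Fraction of mask nodes whose predicted label equals the truth."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    predictions = np.asarray(predictions)
    if predictions.ndim == 2:  # probability rows -> hard labels
        predictions = predictions.argmax(axis=1)
    return float((predictions[mask] == np.asarray(truth)[mask]).mean())


def holdout_split(
    table: EmbeddingTable, test_fraction: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random train/test masks, reproducible by seed.

    Per class, ``round(count * test_fraction)`` nodes go to test, so test
    class proportions match the global ones to within one node per class.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = table.labels
    test = np.zeros(table.n_nodes, dtype=bool)
    for c in np.unique(labels[labels >= 0]):
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            raise ValueError(f"class {c} has fewer than 2 nodes")
        n_test = int(round(idx.size * test_fraction))
        n_test = min(max(n_test, 1), idx.size - 1)
        test[rng.choice(idx, size=n_test, replace=False)] = True
    return ~test, test


def _fit_and_score(
    table: EmbeddingTable,
    graph,
    spec: ModelSpec,
    train_mask: np.ndarray,
    test_mask: np.ndarray,
    train_config: TrainConfig,
) -> float:
    model = build_model(spec, seed=train_config.seed)
    train(model, graph, table, train_mask, train_config)
    probs = predict(model, graph, table.features)
    return accuracy(probs, table.labels, test_mask)


def cross_validate(
    table: EmbeddingTable,
    arch: str = "gcn",
    k: int = 6,
    n_hidden: int = 64,
    heads: int = 10,
    metric: str = "euclidean",
    symmetric: bool = True,
    train_config: TrainConfig | None = None,
) -> EvalResult:
    """Leave-one-fold-out cross-validation over the table's predefined folds.

    For each fold f: train on every node outside f (test labels hidden by
    the mask), score accuracy on f; report the per-fold list with its mean
    and population std.
    """
    if not table.has_folds:
        raise ValueError("table has no fold assignments")
    train_config = train_config or TrainConfig()
    spec = ModelSpec(
        arch=arch,
        d_in=table.d,
        n_hidden=n_hidden,
        n_classes=table.n_classes,
        heads=heads,
    )
    g = knn_edges(table.features, k, metric)
    if symmetric:
        g = symmetrize(g)
    folds = np.unique(table.fold_indices)
    accs, sizes = [], []
    for f in folds:
        test_mask = table.fold_indices == f
        accs.append(
            _fit_and_score(table, g, spec, ~test_mask, test_mask, train_config)
        )
        sizes.append(int(test_mask.sum()))
    accs_arr = np.asarray(accs)
    return EvalResult(
        per_fold_accuracy=[float(a) for a in accs],
        mean=float(accs_arr.mean()),
        std=float(accs_arr.std(ddof=0)),
        n_test_nodes=sizes,
        config={
            "arch": arch,
            "k": k,
            "n_hidden": n_hidden,
            "heads": heads,
            "metric": metric,
            "symmetric": symmetric,
            "epochs": train_config.epochs,
            "lr": train_config.lr,
            "weight_decay": train_config.weight_decay,
            "seed": train_config.seed,
            "std_convention": "population (ddof=0)",
            "n_parameters": count_parameters(build_model(spec, seed=0)),
        },
    )
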