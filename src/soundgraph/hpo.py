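"""Hyperparameter search over k (graph neighbours) and hidden width.

Random search by default (the sampler is pluggable): each trial draws a
(k, n_hidden) pair, trains on an inner train portion carved out of the
*training* data only, and scores on the inner validation portion.  Test
labels are never visible to the objective unless the caller explicitly opts
into ``objective="test"`` for strict replication experiments — that leaks
and is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import _fit_and_score
from .graph import knn_edges, symmetrize
from .io import EmbeddingTable
from .models import ModelSpec
from .training import TrainConfig


@dataclass
class SearchSpace:
    """Integer ranges (inclusive) covering the optima seen in practice:
    k in 3..15, hidden width in 32..256."""

    k_range: tuple[int, int] = (3, 15)
    hidden_range: tuple[int, int] = (32, 256)
    n_trials: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_range[0] > self.k_range[1]:
            raise ValueError("empty k_range")
        if self.hidden_range[0] > self.hidden_range[1]:
            raise ValueError("empty hidden_range")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class Trial:
    k: int
    n_hidden: int
    score: float


@dataclass
class SearchResult:
    best_k: int
    best_hidden: int
    best_score: float
    trials: list[Trial] = field(default_factory=list)


def search(
    table: EmbeddingTable,
    arch: str = "gcn",
    space: SearchSpace | None = None,
    train_config: TrainConfig | None = None,
    *,
    heads: int = 10,
    metric: str = "euclidean",
    symmetric: bool = True,
    val_fraction: float = 0.2,
    objective: str = "val",
    candidates: list[tuple[int, int]] | None = None,
) -> SearchResult:
    """Evaluate ``space.n_trials`` sampled (k, n_hidden) configurations and
    return the argmax with the full trial log; deterministic given the
    space's seed.

    ``candidates`` restricts sampling to an explicit list of (k, n_hidden)
    pairs (useful for exhaustive comparisons).  ``objective="test"`` scores
    on the table's test split instead of an inner validation split; it is
    provided only for replication studies and leaks test labels.
    """
    space = space or SearchSpace()
    train_config = train_config or TrainConfig()
    if objective not in ("val", "test"):
        raise ValueError("objective must be 'val' or 'test'")

    # outer training portion: holdout tables use their train rows; fold
    # tables use all labelled nodes (each CV outer fold would re-run search)
    if not table.has_folds:
        outer_train, outer_test = table.holdout_masks()
    else:
        outer_train = table.labels >= 0
        outer_test = ~outer_train
    if objective == "val":
        # inner split carved from training data only
        rng_split = np.random.default_rng(space.seed)
        labels = table.labels
        val = np.zeros(table.n_nodes, dtype=bool)
        for c in np.unique(labels[outer_train]):
            idx = np.flatnonzero(outer_train & (labels == c))
            n_val = max(1, int(round(idx.size * val_fraction)))
            n_val = min(n_val, idx.size - 1)
            val[rng_split.choice(idx, size=n_val, replace=False)] = True
        fit_mask = outer_train & ~val
        score_mask = val
    else:
        if not outer_test.any():
            raise ValueError("objective='test' needs a test split")
        fit_mask = outer_train
        score_mask = outer_test

    rng = np.random.default_rng(space.seed + 1)
    trials: list[Trial] = []
    graph_cache: dict[int, object] = {}
    for _ in range(space.n_trials):
        if candidates is not None:
            k, hidden = candidates[int(rng.integers(len(candidates)))]
        else:
            k = int(rng.integers(space.k_range[0], space.k_range[1] + 1))
            hidden = int(
                rng.integers(space.hidden_range[0], space.hidden_range[1] + 1)
            )
        if k not in graph_cache:
            g = knn_edges(table.features, k, metric)
            graph_cache[k] = symmetrize(g) if symmetric else g
        spec = ModelSpec(
            arch=arch,
            d_in=table.d,
            n_hidden=hidden,
            n_classes=table.n_classes,
            heads=heads,
        )
        score = _fit_and_score(
            table, graph_cache[k], spec, fit_mask, score_mask, train_config
        )
        trials.append(Trial(k=k, n_hidden=hidden, score=score))

    best = max(trials, key=lambda t: t.score)
    return SearchResult(
        best_k=best.k,
        best_hidden=best.n_hidden,
        best_score=best.score,
        trials=trials,
    )
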