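"""Two-layer GNN models and the estimator-style fitting surface.

The fixed architecture is two message-passing layers with ReLU in between
and dropout (p = 0.5 by default) on each layer's input during training; the
second layer emits raw logits, one per class (softmax lives in the loss).
For GAT the hidden layer runs 10 attention heads whose outputs are
concatenated, and the output layer runs a single head.

Trainable-parameter counts are architecture-determined and exactly
checkable:

* GCN layer:  d_in·d_out + d_out
* SAGE layer: 2·d_in·d_out + d_out
* GAT layer:  2·(d_in·(heads·d_head) + heads·d_head)  (two biased transforms)
              + heads·d_head (attention vector) + heads·d_head (output bias)

``GNNNodeClassifier`` wraps the functional core in a model-object API: build
it from an :class:`~soundgraph.io.EmbeddingTable`, call :meth:`fit`, and read
estimates and diagnostics off the returned :class:`NodeClassifierResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .graph import KnnGraph, knn_edges, symmetrize
from .io import EmbeddingTable
from .layers import (
    GatLayerParams,
    GcnLayerParams,
    SageLayerParams,
    gat_forward,
    gcn_forward,
    identity,
    relu,
    sage_forward,
)

Arch = Literal["gcn", "sage", "gat"]


@dataclass
class ModelSpec:
    """Architecture hyperparameters of a two-layer node classifier.

    ``n_hidden`` is the hidden width (per attention head for GAT); ``heads``
    only applies to GAT's hidden layer — the output layer always uses one
    head.
    """

    arch: Arch
    d_in: int
    n_hidden: int
    n_classes: int
    heads: int = 10
    dropout: float = 0.5

    def __post_init__(self) -> None:
        self.arch = self.arch.lower()
        if self.arch not in ("gcn", "sage", "gat"):
            raise ValueError(f"unknown architecture '{self.arch}'")
        if min(self.d_in, self.n_hidden, self.n_classes) < 1:
            raise ValueError("all dimensions must be positive")
        if self.heads < 1:
            raise ValueError("heads must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


class Model:
    """A built (initialised or trained) two-layer GNN."""

    def __init__(self, spec: ModelSpec, layers: list) -> None:
        self.spec = spec
        self.layers = layers

    # -- parameter plumbing ------------------------------------------------
    def parameter_arrays(self) -> list[np.ndarray]:
        """Flat list of trainable arrays, in a stable order."""
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.extend(layer.arrays())
        return out

    def copy(self) -> "Model":
        import copy

        return copy.deepcopy(self)

    # -- forward -----------------------------------------------------------
    def forward(
        self,
        H: np.ndarray,
        graph: KnnGraph,
        *,
        training: bool = False,
        rng: np.random.Generator | None = None,
        caches: list | None = None,
    ) -> np.ndarray:
        """Full-graph forward pass to logits.

        With ``training=True`` inverted dropout is applied to each layer's
        input (masks drawn from ``rng``) and, when ``caches`` is a list, the
        per-layer caches needed for the backward pass are appended to it.
        """
        spec = self.spec
        H = np.asarray(H, dtype=np.float64)
        X = H
        for i, layer in enumerate(self.layers):
            if training and spec.dropout > 0:
                mask = (rng.random(X.shape) >= spec.dropout) / (1 - spec.dropout)
                X = X * mask
            else:
                mask = None
            if spec.arch == "gcn":
                Z, cache = gcn_forward(X, graph, layer)
            elif spec.arch == "sage":
                Z, cache = sage_forward(X, graph, layer)
            else:
                Z, cache = gat_forward(X, graph, layer)
            act = relu if i == 0 else identity
            out = act(Z)
            if caches is not None:
                caches.append(
                    {"X": X, "Z": Z, "mask": mask, "cache": cache}
                )
            X = out
        return X

    # -- serialisation -----------------------------------------------------
    def save(self, path) -> None:
        blob = {
            "spec": {
                "arch": self.spec.arch,
                "d_in": self.spec.d_in,
                "n_hidden": self.spec.n_hidden,
                "n_classes": self.spec.n_classes,
                "heads": self.spec.heads,
                "dropout": self.spec.dropout,
            },
            "arrays": [arr.tolist() for arr in self.parameter_arrays()],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path) -> "Model":
        with open(path, encoding="utf-8") as fh:
            blob = json.load(fh)
        model = build_model(ModelSpec(**blob["spec"]), seed=0)
        for arr, stored in zip(model.parameter_arrays(), blob["arrays"]):
            arr[...] = np.asarray(stored, dtype=np.float64)
        return model


def build_model(spec: ModelSpec, seed: int = 0) -> Model:
    """Initialise a two-layer model (uniform Glorot weights, zero biases)."""
    rng = np.random.default_rng(seed)
    if spec.arch == "gcn":
        layers = [
            GcnLayerParams.init(spec.d_in, spec.n_hidden, rng),
            GcnLayerParams.init(spec.n_hidden, spec.n_classes, rng),
        ]
    elif spec.arch == "sage":
        layers = [
            SageLayerParams.init(spec.d_in, spec.n_hidden, rng),
            SageLayerParams.init(spec.n_hidden, spec.n_classes, rng),
        ]
    else:
        layers = [
            GatLayerParams.init(
                spec.d_in, spec.n_hidden, spec.heads, concat=True, rng=rng
            ),
            GatLayerParams.init(
                spec.n_hidden * spec.heads,
                spec.n_classes,
                heads=1,
                concat=False,
                rng=rng,
            ),
        ]
    return Model(spec, layers)


def count_parameters(model: Model) -> int:
    """Exact number of trainable scalars in the model."""
    return sum(layer.n_params() for layer in model.layers)


# ==========================================================================
# estimator-style surface
# ==========================================================================
class GNNNodeClassifier:
    """Transductive node classifier over a k-NN audio-embedding graph.

    Parameters
    ----------
    table : EmbeddingTable
        Node features, labels and split assignments.
    arch : {"gcn", "sage", "gat"}
    k : int
        Neighbours per node for graph construction.
    n_hidden : int
        Hidden width (per head for GAT).
    heads : int
        Attention heads in the GAT hidden layer.
    metric : {"euclidean", "cosine"}
    symmetric : bool
        Symmetrise the k-NN digraph (default); the directed graph is kept
        for ablation.

    The graph is built once over *all* nodes — train and test alike — since
    the setting is transductive: unlabeled nodes contribute features and
    edges, never labels.

    Examples
    --------
    >>> table = generate_embeddings(SyntheticSpec(n_nodes=300, seed=1))
    >>> res = GNNNodeClassifier(table, arch="gat", k=6).fit(seed=1)
    >>> res.test_accuracy  # doctest: +SKIP
    0.97
    """

    def __init__(
        self,
        table: EmbeddingTable,
        arch: Arch = "gcn",
        k: int = 6,
        n_hidden: int = 64,
        heads: int = 10,
        dropout: float = 0.5,
        metric: str = "euclidean",
        symmetric: bool = True,
    ) -> None:
        self.table = table
        self.spec = ModelSpec(
            arch=arch,
            d_in=table.d,
            n_hidden=n_hidden,
            n_classes=table.n_classes,
            heads=heads,
            dropout=dropout,
        )
        self.k = k
        self.metric = metric
        self.symmetric = symmetric
        self._graph: KnnGraph | None = None

    @classmethod
    def from_dataframe(cls, df, feature_cols=None, **kwargs):
        """Build from a pandas DataFrame with id/label/fold columns."""
        from .io import EmbeddingTable as _ET

        feature_cols = feature_cols or [
            c for c in df.columns if c not in ("id", "label", "fold")
        ]
        names = sorted(df["label"].astype(str).unique())
        code = {n: i for i, n in enumerate(names)}
        split = (
            df["fold"].to_numpy() if "fold" in df else np.full(len(df), "train")
        )
        table = _ET(
            node_ids=df["id"].astype(str).to_numpy()
            if "id" in df
            else np.arange(len(df)).astype(str),
            features=df[feature_cols].to_numpy(np.float64),
            labels=df["label"].astype(str).map(code).to_numpy(np.int64),
            split=split,
            class_names=names,
        )
        return cls(table, **kwargs)

    @property
    def graph(self) -> KnnGraph:
        if self._graph is None:
            g = knn_edges(self.table.features, self.k, self.metric)
            self._graph = symmetrize(g) if self.symmetric else g
        return self._graph

    def fit(
        self,
        train_mask: np.ndarray | None = None,
        *,
        epochs: int = 300,
        lr: float = 1e-3,
        weight_decay: float = 5e-4,
        seed: int = 0,
    ) -> "NodeClassifierResults":
        """Train by full-batch Adam on cross-entropy over the train mask.

        With no explicit mask, a table carrying a train/test split uses its
        train rows; a fold-structured table trains on every labelled node.
        """
        from .training import TrainConfig, train as _train

        if train_mask is None:
            if not self.table.has_folds:
                train_mask, _ = self.table.holdout_masks()
            else:
                train_mask = self.table.labels >= 0
        config = TrainConfig(
            lr=lr, weight_decay=weight_decay, epochs=epochs, seed=seed
        )
        model = build_model(self.spec, seed=seed)
        trained = _train(model, self.graph, self.table, train_mask, config)
        return NodeClassifierResults(self, trained, np.asarray(train_mask))


class NodeClassifierResults:
    """Fitted-model container: predictions, accuracies and a summary table."""

    def __init__(self, estimator: GNNNodeClassifier, trained, train_mask):
        from .training import predict as _predict

        self.estimator = estimator
        self.model = trained.model
        self.loss_history = trained.loss_history
        self.config = trained.config
        self.train_mask = train_mask
        self._probs = _predict(
            self.model, estimator.graph, estimator.table.features
        )

    # -- estimates ---------------------------------------------------------
    @property
    def probabilities(self) -> np.ndarray:
        """(n_nodes, n_classes) softmax class probabilities."""
        return self._probs

    def predict(self) -> np.ndarray:
        """Hard class labels (argmax of the probabilities)."""
        return self._probs.argmax(axis=1)

    @property
    def n_parameters(self) -> int:
        return count_parameters(self.model)

    def accuracy(self, mask: np.ndarray) -> float:
        from .evaluation import accuracy as _acc

        return _acc(self.predict(), self.estimator.table.labels, mask)

    @property
    def train_accuracy(self) -> float:
        return self.accuracy(self.train_mask)

    @property
    def test_accuracy(self) -> float | None:
        table = self.estimator.table
        if not table.has_folds:
            _, test = table.holdout_masks()
            return self.accuracy(test)
        test = ~self.train_mask
        return self.accuracy(test) if test.any() else None

    def summary(self) -> str:
        """Plain-text summary in the style of statistical model results."""
        spec = self.model.spec
        table = self.estimator.table
        rows = [
            ("Architecture", spec.arch.upper()),
            ("Nodes / features / classes",
             f"{table.n_nodes} / {spec.d_in} / {spec.n_classes}"),
            ("Graph", f"k={self.estimator.k}, {self.estimator.metric}, "
             f"{'symmetric' if self.estimator.symmetric else 'directed'}"),
            ("Hidden width", f"{spec.n_hidden}"
             + (f" x {spec.heads} heads" if spec.arch == "gat" else "")),
            ("Trainable parameters", f"{self.n_parameters:,}"),
            ("Epochs / lr / weight decay",
             f"{self.config.epochs} / {self.config.lr} / "
             f"{self.config.weight_decay}"),
            ("Final training loss",
             f"{self.loss_history[-1]:.4f}" if len(self.loss_history) else "-"),
            ("Training accuracy", f"{self.train_accuracy:.3f}"),
        ]
        test_acc = self.test_accuracy
        if test_acc is not None:
            rows.append(("Held-out accuracy", f"{test_acc:.3f}"))
        width = max(len(r[0]) for r in rows)
        lines = ["Graph Node Classifier Results", "=" * 42]
        lines += [f"{name:<{width}}  {val}" for name, val in rows]
        return "\n".join(lines)
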