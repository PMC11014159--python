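"""Full-batch transductive training.

One gradient step per epoch over the whole graph: every node participates in
message passing, but the cross-entropy loss is computed only over the train
mask, so test labels can never influence a parameter.  Optimisation is Adam
(lr 0.001, weight decay 5e-4 by default, betas 0.9/0.999, eps 1e-8) with a
fixed epoch budget — no early stopping and no schedule.  Weight decay is
applied as an L2 term added to the gradient of every trainable array.

Gradients are hand-derived backward passes through the two layers; they are
validated against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import KnnGraph
from .io import EmbeddingTable
from .layers import gat_backward, gcn_backward, sage_backward
from .models import Model


@dataclass
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 5e-4
    epochs: int = 300
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")


@dataclass
class TrainedModel:
    model: Model
    loss_history: np.ndarray  # per-epoch training loss, length = epochs
    config: TrainConfig


class Adam:
    """Minimal Adam over a list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], config: TrainConfig):
        self.params = params
        self.c = config
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        c = self.c
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g + c.weight_decay * p
            m[...] = c.beta1 * m + (1 - c.beta1) * g
            v[...] = c.beta2 * v + (1 - c.beta2) * g * g
            m_hat = m / (1 - c.beta1**self.t)
            v_hat = v / (1 - c.beta2**self.t)
            p -= c.lr * m_hat / (np.sqrt(v_hat) + c.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def masked_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, mask: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over mask nodes and its gradient wrt logits."""
    idx = np.flatnonzero(mask)
    probs = softmax(logits[idx])
    y = labels[idx]
    loss = float(-np.log(probs[np.arange(len(idx)), y] + 1e-300).mean())
    dlogits = np.zeros_like(logits)
    g = probs.copy()
    g[np.arange(len(idx)), y] -= 1.0
    dlogits[idx] = g / len(idx)
    return loss, dlogits


def _layer_backward(arch: str, dZ, layer, state):
    if arch == "gcn":
        dX, grads = gcn_backward(dZ, state["X"], layer, state["cache"])
        order = ["W", "bias"]
    elif arch == "sage":
        dX, grads = sage_backward(dZ, state["X"], layer, state["cache"])
        order = ["W", "B", "bias"]
    else:
        dX, grads = gat_backward(dZ, state["X"], layer, state["cache"])
        order = ["W_l", "b_l", "W_r", "b_r", "a", "out_bias"]
    return dX, [grads[k] for k in order]


def loss_and_grads(
    model: Model,
    graph: KnnGraph,
    features: np.ndarray,
    labels: np.ndarray,
    train_mask: np.ndarray,
    rng: np.random.Generator | None = None,
    training: bool = True,
) -> tuple[float, list[np.ndarray]]:
    """One forward/backward pass; returns (loss, grads aligned with
    model.parameter_arrays())."""
    caches: list = []
    logits = model.forward(
        features, graph, training=training, rng=rng, caches=caches
    )
    loss, dZ2 = masked_cross_entropy(logits, labels, train_mask)

    arch = model.spec.arch
    # layer 2 (identity activation)
    dX, grads2 = _layer_backward(arch, dZ2, model.layers[1], caches[1])
    if caches[1]["mask"] is not None:
        dX = dX * caches[1]["mask"]
    # through ReLU at layer-1 output
    dZ1 = dX * (caches[0]["Z"] > 0)
    _, grads1 = _layer_backward(arch, dZ1, model.layers[0], caches[0])
    return loss, grads1 + grads2


def train(
    model: Model,
    graph: KnnGraph,
    table: EmbeddingTable,
    train_mask: np.ndarray,
    config: TrainConfig,
) -> TrainedModel:
    """Train in place; returns the model with its per-epoch loss history.

    The train mask must be nonempty and contain every class at least once.
    """
    features = table.features
    labels = table.labels
    train_mask = np.asarray(train_mask, dtype=bool)
    if not train_mask.any():
        raise ValueError("train_mask is empty")
    present = np.unique(labels[train_mask])
    expected = np.arange(model.spec.n_classes)
    if not np.array_equal(present, expected):
        missing = sorted(int(c) for c in set(expected) - set(present))
        raise ValueError(
            f"classes {missing} missing from train_mask; the loss would "
            "silently ignore them"
        )
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameter_arrays(), config)
    history = np.empty(config.epochs)
    for epoch in range(config.epochs):
        loss, grads = loss_and_grads(
            model, graph, features, labels, train_mask, rng=rng
        )
        opt.step(grads)
        history[epoch] = loss
    return TrainedModel(model=model, loss_history=history, config=config)


def predict(
    model: Model, graph: KnnGraph, features: np.ndarray
) -> np.ndarray:
    """Per-node class probabilities (dropout disabled); rows sum to 1."""
    logits = model.forward(np.asarray(features), graph, training=False)
    return softmax(logits)
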