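"""Synthetic embedding tables with the structure the pipeline assumes.

Real deep-audio embeddings of recordings from the same sound class cluster in
feature space; the k-NN graph is informative exactly to the extent that they
do.  The generator emulates this with class-conditional isotropic Gaussians
whose means sit at scaled simplex vertices, so every pair of class means is
the same distance apart and a single knob (``class_sep``, in units of the
noise standard deviation) controls difficulty: 0 means label-free features,
8+ means nearly separated clusters.

Fold or train/test assignment is deterministic and stratified, so fold-level
class proportions match the global ones to within one node per class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EmbeddingTable

#: Class proportions of a strongly imbalanced three-cover soundscape
#: (forest / savanna / pasture at roughly 20/21/59%), for imbalance tests.
REY_ZAMURO_PROPORTIONS = (14546 / 71497, 14994 / 71497, 41957 / 71497)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic embedding table.

    ``n_folds`` selects predefined-fold cross-validation splits (1-based,
    UrbanSound8K-style); ``holdout_fraction`` selects a train/test split
    instead.  Exactly one of the two applies; ``n_folds`` wins if both set.
    """

    n_nodes: int = 300
    d: int = 32
    n_classes: int = 3
    class_sep: float = 8.0
    noise_sd: float = 1.0
    class_proportions: tuple[float, ...] | None = None
    n_folds: int | None = None
    holdout_fraction: float | None = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_sep < 0:
            raise ValueError("class_sep must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_nodes < self.n_classes:
            raise ValueError("need at least one node per class")
        if self.d < self.n_classes:
            raise ValueError("need d >= n_classes to place equidistant means")
        if self.class_proportions is None:
            self.class_proportions = tuple(
                [1.0 / self.n_classes] * self.n_classes
            )
        props = np.asarray(self.class_proportions, dtype=float)
        if len(props) != self.n_classes or (props < 0).any():
            raise ValueError("class_proportions must be n_classes nonnegatives")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if self.n_folds is None and self.holdout_fraction is None:
            raise ValueError("one of n_folds / holdout_fraction is required")
        if self.holdout_fraction is not None and not (
            0 < self.holdout_fraction < 1
        ):
            raise ValueError("holdout_fraction must be in (0, 1)")


def _class_counts(n: int, props: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n nodes to classes."""
    raw = props * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    return counts


def _class_means(C: int, d: int, sep: float) -> np.ndarray:
    # Scaled standard-basis vertices: |e_i - e_j| = sqrt(2), so scaling by
    # sep/sqrt(2) puts every pair of means exactly `sep` apart.
    means = np.zeros((C, d))
    means[np.arange(C), np.arange(C)] = sep / np.sqrt(2.0)
    return means - means.mean(axis=0)


def generate_embeddings(spec: SyntheticSpec) -> EmbeddingTable:
    """Draw a fully reproducible synthetic embedding table.

    Labels are laid out class-by-class; features are
    ``mean[label] + noise_sd * N(0, I)``; folds (or the test flag) are dealt
    round-robin within each class so stratification is exact.
    """
    rng = np.random.default_rng(spec.seed)
    props = np.asarray(spec.class_proportions, dtype=float)
    counts = _class_counts(spec.n_nodes, props)
    if (counts == 0).any():
        raise ValueError("a class received zero nodes; increase n_nodes")
    labels = np.repeat(np.arange(spec.n_classes), counts)
    means = _class_means(spec.n_classes, spec.d, spec.class_sep * spec.noise_sd)
    feats = means[labels] + spec.noise_sd * rng.standard_normal(
        (spec.n_nodes, spec.d)
    )

    split: np.ndarray
    if spec.n_folds is not None:
        split = np.empty(spec.n_nodes, dtype=np.int64)
        for c in range(spec.n_classes):
            idx = np.flatnonzero(labels == c)
            split[idx] = (np.arange(idx.size) % spec.n_folds) + 1
    else:
        split = np.full(spec.n_nodes, "train", dtype="U5")
        for c in range(spec.n_classes):
            idx = np.flatnonzero(labels == c)
            n_test = int(round(idx.size * spec.holdout_fraction))
            # deal test membership evenly through the class block
            if n_test:
                pick = np.linspace(0, idx.size - 1, n_test).round().astype(int)
                split[idx[np.unique(pick)]] = "test"

    ids = np.array([f"clip{i:05d}" for i in range(spec.n_nodes)])
    names = [f"class{c}" for c in range(spec.n_classes)]
    return EmbeddingTable(
        node_ids=ids,
        features=feats,
        labels=labels,
        split=split,
        class_names=names,
    )
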