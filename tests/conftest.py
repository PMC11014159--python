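import numpy as np
import pytest

import soundgraph as sg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """Tiny holdout table: 60 nodes, 3 well-separated classes, 8 dims."""
    return sg.generate_embeddings(
        sg.SyntheticSpec(
            n_nodes=60, d=8, n_classes=3, class_sep=8.0, seed=7
        )
    )


@pytest.fixture
def fold_table():
    """Fold-structured table: 200 nodes, 4 folds, separable classes."""
    return sg.generate_embeddings(
        sg.SyntheticSpec(
            n_nodes=200,
            d=8,
            n_classes=3,
            class_sep=10.0,
            n_folds=4,
            holdout_fraction=None,
            seed=11,
        )
    )


@pytest.fixture
def random_graph(rng):
    """Random symmetrised k-NN graph over 15 nodes with features."""
    X = rng.standard_normal((15, 6))
    g = sg.symmetrize(sg.knn_edges(X, 3))
    return X, g
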