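"""Message-passing layers against dense/naive oracles, plus the structural
invariants: attention normalisation, permutation equivariance, locality."""

import numpy as np
import pytest

import soundgraph as sg
from soundgraph.layers import identity, leaky_relu
from soundgraph.models import build_model

# --------------------------------------------------------------------------
# naive oracles: literal per-node / dense-matrix evaluations
# --------------------------------------------------------------------------


def dense_gcn_oracle(H, g, params):
    n = g.n_nodes
    A = g.adjacency().toarray()
    At = A.T + np.eye(n)  # in-neighbour orientation + self-loops
    D = np.diag(At.sum(axis=1))
    D_inv_sqrt = np.diag(1.0 / np.sqrt(np.diag(D)))
    return D_inv_sqrt @ At @ D_inv_sqrt @ H @ params.W + params.bias


def naive_sage_oracle(H, g, params):
    out = np.zeros((g.n_nodes, params.W.shape[1]))
    for u in range(g.n_nodes):
        nbrs = g.in_neighbors(u)
        agg = H[nbrs].mean(axis=0) if len(nbrs) else np.zeros(H.shape[1])
        out[u] = agg @ params.W + H[u] @ params.B + params.bias
    return out


def naive_gat_oracle(H, g, params):
    """Literal per-node, per-head attention loop."""
    n = g.n_nodes
    heads, dh = params.heads, params.d_head
    Gl = (H @ params.W_l + params.b_l).reshape(n, heads, dh)
    Gr = (H @ params.W_r + params.b_r).reshape(n, heads, dh)
    a = params.a.reshape(heads, dh)
    O = np.zeros((n, heads, dh))
    alpha_all = {}
    for u in range(n):
        nbrs = sorted(set(g.in_neighbors(u).tolist()) | {u})
        for h in range(heads):
            scores = []
            for v in nbrs:
                t = leaky_relu(Gl[u, h] + Gr[v, h], params.leaky_slope)
                scores.append(a[h] @ t)
            scores = np.array(scores)
            ex = np.exp(scores - scores.max())
            alpha = ex / ex.sum()
            for v, al in zip(nbrs, alpha):
                alpha_all[(u, v, h)] = al
                O[u, h] += al * Gr[v, h]
    if params.concat:
        Z = O.reshape(n, heads * dh) + params.out_bias
    else:
        Z = O.mean(axis=1) + params.out_bias
    return Z, alpha_all


def random_instance(rng, n=15, d_in=6, d_out=4, arch="gcn", heads=3):
    X = rng.standard_normal((n, d_in))
    g = sg.symmetrize(sg.knn_edges(X, 3))
    if arch == "gcn":
        params = sg.GcnLayerParams.init(d_in, d_out, rng)
    elif arch == "sage":
        params = sg.SageLayerParams.init(d_in, d_out, rng)
    else:
        params = sg.GatLayerParams.init(
            d_in, d_out, heads, concat=True, rng=rng
        )
    return X, g, params


# --------------------------------------------------------------------------
# GCN
# --------------------------------------------------------------------------
class TestGcnLayer:
    def test_single_isolated_node_reduces_to_affine(self, rng):
        g = sg.KnnGraph(n_nodes=1, edges=np.empty((0, 2), int), k=0)
        params = sg.GcnLayerParams.init(4, 3, rng)
        H = rng.standard_normal((1, 4))
        out = sg.gcn_layer(H, g, params, activation=identity)
        np.testing.assert_allclose(out, H @ params.W + params.bias)

    def test_zero_weights_annihilate(self, random_graph):
        X, g = random_graph
        params = sg.GcnLayerParams(W=np.zeros((6, 3)), bias=np.zeros(3))
        out = sg.gcn_layer(X, g, params)
        np.testing.assert_array_equal(out, 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X, g, params = random_instance(rng, arch="gcn")
        out = sg.gcn_layer(X, g, params, activation=identity)
        np.testing.assert_allclose(
            out, dense_gcn_oracle(X, g, params), atol=1e-6
        )

    def test_shape_mismatch_rejected(self, random_graph, rng):
        X, g = random_graph
        params = sg.GcnLayerParams.init(99, 3, rng)
        with pytest.raises(ValueError):
            sg.gcn_layer(X, g, params)


# --------------------------------------------------------------------------
# GraphSAGE
# --------------------------------------------------------------------------
class TestSageLayer:
    def test_isolated_node_keeps_self_term_only(self, rng):
        g = sg.KnnGraph(n_nodes=2, edges=[[0, 1]], k=1)  # node 0 isolated-in
        params = sg.SageLayerParams.init(4, 3, rng)
        H = rng.standard_normal((2, 4))
        out = sg.sage_layer(H, g, params, activation=identity)
        np.testing.assert_allclose(out[0], H[0] @ params.B + params.bias)

    def test_identity_neighbor_transform_copies_neighbor(self):
        g = sg.KnnGraph(n_nodes=2, edges=[[0, 1]], k=1)
        params = sg.SageLayerParams(
            W=np.eye(3), B=np.zeros((3, 3)), bias=np.zeros(3)
        )
        H = np.array([[1.0, 2.0, 3.0], [9.0, 9.0, 9.0]])
        out = sg.sage_layer(H, g, params, activation=identity)
        np.testing.assert_allclose(out[1], H[0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X, g, params = random_instance(rng, arch="sage")
        out = sg.sage_layer(X, g, params, activation=identity)
        np.testing.assert_allclose(
            out, naive_sage_oracle(X, g, params), atol=1e-6
        )


# --------------------------------------------------------------------------
# GAT
# --------------------------------------------------------------------------
class TestAttention:
    def test_singleton_neighborhood_gets_full_weight(self, rng):
        g = sg.KnnGraph(n_nodes=2, edges=[[0, 1]], k=1)  # node 0: self only
        params = sg.GatLayerParams.init(4, 3, heads=2, concat=True, rng=rng)
        H = rng.standard_normal((2, 4))
        alpha, src, tgt = sg.attention_coefficients(H, g, params)
        self_edge = (src == 0) & (tgt == 0)
        np.testing.assert_allclose(alpha[self_edge], 1.0)

    def test_identical_features_split_evenly(self, rng):
        # both in-neighbours of node 2 carry the same features as node 2
        # itself, so all three (incl. self-loop) coefficients are 1/3
        g = sg.KnnGraph(n_nodes=3, edges=[[0, 2], [1, 2]], k=2)
        params = sg.GatLayerParams.init(4, 3, heads=2, concat=True, rng=rng)
        H = np.tile(np.array([[0.3, -1.2, 0.7, 2.0]]), (3, 1))
        alpha, src, tgt = sg.attention_coefficients(H, g, params)
        np.testing.assert_allclose(alpha[tgt == 2], 1 / 3, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_softmax_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X, g, params = random_instance(rng, n=10, arch="gat")
        alpha, src, tgt = sg.attention_coefficients(X, g, params)
        _, oracle = naive_gat_oracle(X, g, params)
        for e in range(len(src)):
            for h in range(params.heads):
                assert alpha[e, h] == pytest.approx(
                    oracle[(tgt[e], src[e], h)], abs=1e-9
                )

    @pytest.mark.parametrize("seed", range(5))
    def test_normalisation_sums_to_one(self, seed):
        rng = np.random.default_rng(100 + seed)
        X, g, params = random_instance(rng, n=20, arch="gat")
        alpha, src, tgt = sg.attention_coefficients(X, g, params)
        for u in range(g.n_nodes):
            sums = alpha[tgt == u].sum(axis=0)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)


class TestGatLayer:
    def test_identical_features_give_identical_rows(self, rng):
        X = np.tile(rng.standard_normal((1, 5)), (8, 1))
        g = sg.symmetrize(sg.knn_edges(np.arange(8)[:, None] * 1.0, 2))
        params = sg.GatLayerParams.init(5, 4, heads=2, concat=True, rng=rng)
        out = sg.gat_layer(X, g, params, activation=identity)
        np.testing.assert_allclose(out, np.tile(out[0], (8, 1)), atol=1e-12)

    def test_uniform_attention_reduces_to_mean(self, rng):
        # identical features force uniform alpha; single head output is the
        # mean of the transformed (identical) neighbours = the transform
        g = sg.KnnGraph(n_nodes=3, edges=[[0, 2], [1, 2]], k=2)
        params = sg.GatLayerParams.init(4, 4, heads=1, concat=True, rng=rng)
        H = np.tile(rng.standard_normal((1, 4)), (3, 1))
        out = sg.gat_layer(H, g, params, activation=identity)
        expect = H[0] @ params.W_r + params.b_r + params.out_bias
        np.testing.assert_allclose(out[2], expect, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X, g, params = random_instance(rng, arch="gat")
        out = sg.gat_layer(X, g, params, activation=identity)
        oracle, _ = naive_gat_oracle(X, g, params)
        np.testing.assert_allclose(out, oracle, atol=1e-6)

    def test_average_heads_output_layer(self, rng):
        X, g, _ = random_instance(rng, arch="gcn")
        params = sg.GatLayerParams.init(6, 4, heads=3, concat=False, rng=rng)
        out = sg.gat_layer(X, g, params, activation=identity)
        oracle, _ = naive_gat_oracle(X, g, params)
        assert out.shape == (15, 4)
        np.testing.assert_allclose(out, oracle, atol=1e-6)


# --------------------------------------------------------------------------
# shared structural invariants
# --------------------------------------------------------------------------
def _layer_output(arch, X, g, seed):
    rng = np.random.default_rng(seed)
    if arch == "gcn":
        p = sg.GcnLayerParams.init(X.shape[1], 4, rng)
        return sg.gcn_layer(X, g, p, activation=identity)
    if arch == "sage":
        p = sg.SageLayerParams.init(X.shape[1], 4, rng)
        return sg.sage_layer(X, g, p, activation=identity)
    p = sg.GatLayerParams.init(X.shape[1], 4, 2, concat=True, rng=rng)
    return sg.gat_layer(X, g, p, activation=identity)


@pytest.mark.parametrize("arch", ["gcn", "sage", "gat"])
def test_permutation_equivariance(arch):
    rng = np.random.default_rng(3)
    X = rng.standard_normal((18, 5))
    g = sg.symmetrize(sg.knn_edges(X, 3))
    perm = rng.permutation(18)
    g_perm = sg.symmetrize(sg.knn_edges(X[perm], 3))
    out = _layer_output(arch, X, g, seed=9)
    out_perm = _layer_output(arch, X[perm], g_perm, seed=9)
    np.testing.assert_allclose(out_perm, out[perm], atol=1e-9)


@pytest.mark.parametrize("arch", ["gcn", "sage", "gat"])
def test_two_hop_locality(arch):
    """Editing features outside u's 2-hop in-neighbourhood cannot change a
    two-layer model's output at u."""
    rng = np.random.default_rng(4)
    X = rng.standard_normal((40, 6))
    g = sg.symmetrize(sg.knn_edges(X, 2))
    spec = sg.ModelSpec(
        arch=arch, d_in=6, n_hidden=5, n_classes=3, heads=2, dropout=0.0
    )
    model = build_model(spec, seed=1)
    u = 0
    hop1 = set(g.in_neighbors(u).tolist()) | {u}
    hop2 = set(hop1)
    for v in hop1:
        hop2 |= set(g.in_neighbors(v).tolist())
    outside = [v for v in range(40) if v not in hop2]
    assert outside, "fixture must leave nodes outside the 2-hop ball"
    base = model.forward(X, g)[u]
    X2 = X.copy()
    X2[outside] += rng.standard_normal((len(outside), 6)) * 5
    # same graph: locality is a property of message passing, the graph is held fixed
    perturbed = model.forward(X2, g)[u]
    np.testing.assert_allclose(perturbed, base, atol=1e-9)
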