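"""From-scratch message-passing layers: GCN, GraphSAGE and GAT.

All three layers share the neural message-passing template: node u's next
embedding is an update of its current embedding with an aggregation of its
in-neighbourhood N_u.  They differ in the aggregation:

* GCN — symmetrically degree-normalised sum over N_u plus a self-loop,
  ``act(D^{-1/2}(A+I)D^{-1/2} H W + b)``.
* GraphSAGE — mean over N_u transformed by W, plus the node's own features
  transformed by a separate matrix B (no self-loop in the aggregation);
  the summed-block form is parameter-identical to concatenating the
  aggregated neighbourhood with the self features.
* GAT — attention-weighted sum over N_u ∪ {u}: per head, the unnormalised
  score of edge (v -> u) is ``a · LeakyReLU(W_l h_u + W_r h_v)`` with slope
  0.2, normalised by a softmax over u's neighbourhood, and the value is the
  transformed source embedding.  Multi-head outputs are concatenated in
  hidden layers and used singly (one head) in the output layer.

Each layer has a pure functional forward (the public API checked against
dense/naive oracles in the tests) and a backward pass used by the trainer;
gradients are hand-derived and validated by finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import KnnGraph, gcn_propagation, mean_aggregation

LEAKY_SLOPE = 0.2  # fixed LeakyReLU slope for attention scoring


# --------------------------------------------------------------------------
# activations
# --------------------------------------------------------------------------
def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def identity(x: np.ndarray) -> np.ndarray:
    return x


def leaky_relu(x: np.ndarray, slope: float = LEAKY_SLOPE) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------
@dataclass
class GcnLayerParams:
    W: np.ndarray  # (d_in, d_out)
    bias: np.ndarray  # (d_out,)

    @classmethod
    def init(cls, d_in: int, d_out: int, rng: np.random.Generator):
        return cls(
            W=_glorot(rng, d_in, d_out, (d_in, d_out)),
            bias=np.zeros(d_out),
        )

    def arrays(self):
        return [self.W, self.bias]

    def n_params(self) -> int:
        return self.W.size + self.bias.size


@dataclass
class SageLayerParams:
    """Neighbour transform W carries the single bias; self transform B
    does not — per-layer count is 2·d_in·d_out + d_out."""

    W: np.ndarray  # (d_in, d_out) neighbour-aggregate transform
    B: np.ndarray  # (d_in, d_out) self transform
    bias: np.ndarray  # (d_out,)

    @classmethod
    def init(cls, d_in: int, d_out: int, rng: np.random.Generator):
        return cls(
            W=_glorot(rng, d_in, d_out, (d_in, d_out)),
            B=_glorot(rng, d_in, d_out, (d_in, d_out)),
            bias=np.zeros(d_out),
        )

    def arrays(self):
        return [self.W, self.B, self.bias]

    def n_params(self) -> int:
        return self.W.size + self.B.size + self.bias.size


@dataclass
class GatLayerParams:
    """Two separate biased input transforms — W_l applied to the target
    (attending) node, W_r to the source (attended) node — plus an attention
    vector of length heads·d_head and an additive output bias."""

    W_l: np.ndarray  # (d_in, heads*d_head), target transform
    b_l: np.ndarray  # (heads*d_head,)
    W_r: np.ndarray  # (d_in, heads*d_head), source transform (also values)
    b_r: np.ndarray  # (heads*d_head,)
    a: np.ndarray  # (heads*d_head,) attention vector
    out_bias: np.ndarray  # (heads*d_head,) if concat else (d_head,)
    heads: int
    concat: bool = True
    leaky_slope: float = LEAKY_SLOPE

    @classmethod
    def init(
        cls,
        d_in: int,
        d_head: int,
        heads: int,
        concat: bool,
        rng: np.random.Generator,
    ):
        hd = heads * d_head
        return cls(
            W_l=_glorot(rng, d_in, hd, (d_in, hd)),
            b_l=np.zeros(hd),
            W_r=_glorot(rng, d_in, hd, (d_in, hd)),
            b_r=np.zeros(hd),
            a=_glorot(rng, d_head, 1, (hd,)),
            out_bias=np.zeros(hd if concat else d_head),
            heads=heads,
            concat=concat,
        )

    @property
    def d_head(self) -> int:
        return self.W_l.shape[1] // self.heads

    def arrays(self):
        return [self.W_l, self.b_l, self.W_r, self.b_r, self.a, self.out_bias]

    def n_params(self) -> int:
        return sum(arr.size for arr in self.arrays())


# --------------------------------------------------------------------------
# GCN
# --------------------------------------------------------------------------
def gcn_forward(H, graph: KnnGraph, params: GcnLayerParams, S=None):
    """Pre-activation GCN propagation; returns (Z, cache)."""
    if S is None:
        S = gcn_propagation(graph)
    SH = S @ H
    Z = SH @ params.W + params.bias
    return Z, {"S": S, "SH": SH}


def gcn_backward(dZ, H, params: GcnLayerParams, cache):
    dW = cache["SH"].T @ dZ
    db = dZ.sum(axis=0)
    dH = cache["S"].T @ (dZ @ params.W.T)
    return dH, {"W": dW, "bias": db}


def gcn_layer(H, graph: KnnGraph, params: GcnLayerParams, activation=relu):
    """act(D^{-1/2}(A+I)D^{-1/2} H W + b), by sparse neighbour aggregation."""
    H = np.asarray(H, dtype=np.float64)
    if H.shape[0] != graph.n_nodes or H.shape[1] != params.W.shape[0]:
        raise ValueError("feature matrix shape inconsistent with layer")
    Z, _ = gcn_forward(H, graph, params)
    return activation(Z)


# --------------------------------------------------------------------------
# GraphSAGE
# --------------------------------------------------------------------------
def sage_forward(H, graph: KnnGraph, params: SageLayerParams, M=None):
    if M is None:
        M = mean_aggregation(graph)
    MH = M @ H
    Z = MH @ params.W + H @ params.B + params.bias
    return Z, {"M": M, "MH": MH}


def sage_backward(dZ, H, params: SageLayerParams, cache):
    dW = cache["MH"].T @ dZ
    dB = H.T @ dZ
    db = dZ.sum(axis=0)
    dH = cache["M"].T @ (dZ @ params.W.T) + dZ @ params.B.T
    return dH, {"W": dW, "B": dB, "bias": db}


def sage_layer(H, graph: KnnGraph, params: SageLayerParams, activation=relu):
    """act(W·mean_{v∈N_u} h_v + B·h_u + b); isolated nodes aggregate zero."""
    H = np.asarray(H, dtype=np.float64)
    if H.shape[0] != graph.n_nodes or H.shape[1] != params.W.shape[0]:
        raise ValueError("feature matrix shape inconsistent with layer")
    Z, _ = sage_forward(H, graph, params)
    return activation(Z)


# --------------------------------------------------------------------------
# GAT
# --------------------------------------------------------------------------
def _gat_edges(graph: KnnGraph):
    """Self-looped edge arrays sorted by target, reduceat boundaries, and
    scatter (incidence) matrices for fast segment sums.

    Every node gains the loop (u, u), so every softmax segment is nonempty
    and segments appear in node order 0..n-1.  ``T_inc`` (resp. ``S_inc``)
    is the (n, E) matrix summing edge quantities into their target (resp.
    source) node; cached on the graph since it is structure-only.
    """
    cached = getattr(graph, "_gat_cache", None)
    if cached is not None:
        return cached
    import scipy.sparse as sp

    src, tgt = graph.edge_arrays(add_self_loops=True)
    order = np.lexsort((src, tgt))
    src, tgt = src[order], tgt[order]
    starts = np.searchsorted(tgt, np.arange(graph.n_nodes))
    E = src.size
    ones = np.ones(E)
    T_inc = sp.csr_matrix(
        (ones, (tgt, np.arange(E))), shape=(graph.n_nodes, E)
    )
    S_inc = sp.csr_matrix(
        (ones, (src, np.arange(E))), shape=(graph.n_nodes, E)
    )
    cache = (src, tgt, starts, T_inc, S_inc)
    graph._gat_cache = cache
    return cache


def _segment_softmax(logits, tgt, starts, n):
    """Softmax over edges grouped by target node, per head; numerically
    stabilised by subtracting the per-segment maximum."""
    seg_max = np.maximum.reduceat(logits, starts, axis=0)
    ex = np.exp(logits - seg_max[tgt])
    seg_sum = np.add.reduceat(ex, starts, axis=0)
    return ex / seg_sum[tgt]


def gat_forward(H, graph: KnnGraph, params: GatLayerParams, edge_cache=None):
    """Pre-activation multi-head attention aggregation; returns (Z, cache)."""
    n = graph.n_nodes
    heads, dh = params.heads, params.d_head
    if edge_cache is None:
        edge_cache = _gat_edges(graph)
    src, tgt, starts, T_inc, S_inc = edge_cache
    E = src.size
    Gl = (H @ params.W_l + params.b_l).reshape(n, heads, dh)
    Gr = (H @ params.W_r + params.b_r).reshape(n, heads, dh)
    S = Gl[tgt] + Gr[src]  # (E, heads, dh)
    T = leaky_relu(S, params.leaky_slope)
    logits = np.einsum("ehd,hd->eh", T, params.a.reshape(heads, dh))
    alpha = _segment_softmax(logits, tgt, starts, n)
    vals = Gr[src]  # values: transformed source embeddings
    O = (T_inc @ (alpha[:, :, None] * vals).reshape(E, -1)).reshape(
        n, heads, dh
    )
    if params.concat:
        Z = O.reshape(n, heads * dh) + params.out_bias
    else:
        Z = O.mean(axis=1) + params.out_bias
    cache = {
        "Gl": Gl, "Gr": Gr, "S": S, "T": T, "alpha": alpha,
        "src": src, "tgt": tgt, "starts": starts,
        "T_inc": T_inc, "S_inc": S_inc,
    }
    return Z, cache


def gat_backward(dZ, H, params: GatLayerParams, cache):
    n = H.shape[0]
    heads, dh = params.heads, params.d_head
    src, tgt, starts = cache["src"], cache["tgt"], cache["starts"]
    alpha, Gr, T, S = cache["alpha"], cache["Gr"], cache["T"], cache["S"]

    if params.concat:
        dO = dZ.reshape(n, heads, dh)
        d_out_bias = dZ.sum(axis=0)
    else:
        dO = np.repeat(dZ[:, None, :], heads, axis=1) / heads
        d_out_bias = dZ.sum(axis=0)

    vals = Gr[src]
    dO_t = dO[tgt]  # (E, heads, dh)
    dalpha = np.einsum("ehd,ehd->eh", dO_t, vals)
    dvals = alpha[:, :, None] * dO_t

    # softmax backward per segment: de = alpha * (dalpha - sum_seg alpha*dalpha)
    seg_c = np.add.reduceat(alpha * dalpha, starts, axis=0)  # (n, heads)
    de = alpha * (dalpha - seg_c[tgt])

    a_h = params.a.reshape(heads, dh)
    dT = de[:, :, None] * a_h[None, :, :]
    da = np.einsum("eh,ehd->hd", de, T).reshape(-1)
    dS = dT * np.where(S >= 0, 1.0, params.leaky_slope)

    E = src.size
    T_inc, S_inc = cache["T_inc"], cache["S_inc"]
    dGl = (T_inc @ dS.reshape(E, -1)).reshape(n, heads, dh)
    dGr = (S_inc @ (dS + dvals).reshape(E, -1)).reshape(n, heads, dh)

    dGl2, dGr2 = dGl.reshape(n, -1), dGr.reshape(n, -1)
    grads = {
        "W_l": H.T @ dGl2,
        "b_l": dGl2.sum(axis=0),
        "W_r": H.T @ dGr2,
        "b_r": dGr2.sum(axis=0),
        "a": da,
        "out_bias": d_out_bias,
    }
    dH = dGl2 @ params.W_l.T + dGr2 @ params.W_r.T
    return dH, grads


def attention_coefficients(H, graph: KnnGraph, params: GatLayerParams):
    """Per-edge attention coefficients alpha_uv, shape (E, heads).

    Returns ``(alpha, sources, targets)`` over the self-looped edge set;
    for every target u and head, the coefficients over N_u ∪ {u} sum to 1.
    """
    H = np.asarray(H, dtype=np.float64)
    _, cache = gat_forward(H, graph, params)
    return cache["alpha"], cache["src"], cache["tgt"]


def gat_layer(
    H,
    graph: KnnGraph,
    params: GatLayerParams,
    activation=relu,
):
    """Attention aggregation: per head, act(sum_v alpha_uv (W_r h_v) + bias);
    heads concatenated (hidden layer) or averaged (output layer)."""
    H = np.asarray(H, dtype=np.float64)
    if H.shape[0] != graph.n_nodes or H.shape[1] != params.W_l.shape[0]:
        raise ValueError("feature matrix shape inconsistent with layer")
    Z, _ = gat_forward(H, graph, params)
    return activation(Z)
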