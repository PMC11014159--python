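# Methods

## Setting and model

`soundgraph` performs transductive node classification over a k-nearest-
neighbour graph of audio-recording embeddings.  Nodes are recordings, node
features are fixed-length deep-embedding vectors (128/1024/2048 dimensions
for the VGGish/YAMNet/PANNs extractor families; extractors themselves are
out of scope — the package consumes their output tables).  Edges connect
each recording to its k nearest neighbours in embedding space; the graph is
built once over *all* nodes, train and test alike, so unlabeled nodes
contribute connectivity but never labels.

Segment-level extractors emit one vector per ~1 s window; `average_segments`
/ `collapse_segments` reduce a recording's window matrix to one clip-level
vector by the column-wise arithmetic mean.  Rows already clip-level pass
through unchanged, which keeps the package agnostic about which extractor
families were segment-averaged upstream.

### Graph construction

Distances are computed exactly (dense pairwise table; no approximate index
at these scales), with Euclidean default and cosine available because deep
embeddings are often compared by angle.  Equal distances are broken toward
the lower node index so construction is fully deterministic.  The raw k-NN
digraph gives every node exactly k in-neighbours; by default the edge set
is symmetrised (union with its reverse), because the GCN's symmetric
normalisation `D̃^(-1/2)(A+I)D̃^(-1/2)` presumes an undirected adjacency.
The directed graph is retained behind a flag for ablation; there, operators
are built over the in-neighbour orientation so each node still aggregates
its own k nearest neighbours.

### Layers

All three layers instantiate neural message passing — aggregate the
neighbourhood, update the node — and differ only in the aggregator:

- **GCN**: `act(D̃^(-1/2) Ã D̃^(-1/2) H W + b)`, Ã = A + I (self-loops in
  the operator, not the edge set).
- **GraphSAGE**: `act(W·mean_{v∈N_u} h_v + B·h_u + b)`.  The mean
  aggregator is used (the only choice consistent with the published
  parameter counts); the summed-block form is parameter-identical to
  concatenating aggregated-neighbourhood and self features.  No self-loop
  is added — the self term is explicit — and an isolated node aggregates
  the zero vector.  The neighbour transform carries the single bias, the
  self transform none (again fixed by the published counts).
- **GAT**: per head, edge score `e_uv = aᵀ LeakyReLU(W_l h_u + W_r h_v)`
  with slope 0.2, softmax-normalised over N_u ∪ {u} (a self-loop is always
  inserted, so every softmax is well defined), and output
  `Σ_v α_uv (W_r h_v)` — the source transform doubles as the value map, so
  its bias contributes a constant shift because the coefficients sum to 1.
  Hidden layer: 10 heads, outputs concatenated; output layer: 1 head.
  Two *separate* biased input transforms (target-side W_l, source-side W_r)
  are used rather than one shared transform on concatenated features: the
  two-transform convention is what the published trainable-parameter counts
  imply (per layer, `2·(d_in·h·d + h·d) + h·d` attention + `h·d` output
  bias with h heads of width d), and it is the convention this package
  adopts throughout.  A shared-transform variant is deliberately not
  implemented: it would change the parameter count, complicate the
  hand-derived backward pass, and nothing downstream exercises it.

Models are exactly two layers: ReLU after layer 1, raw logits from layer 2
(softmax lives in the loss), inverted dropout p = 0.5 applied to both
layers' inputs during training only.  Initialisation is uniform Glorot for
weight matrices and the attention vector, zeros for biases, seed-controlled;
the procedure the package mirrors is silent on initialisation, so this is a
package choice.

### Training

Full-batch gradient descent — one Adam step per epoch over the whole graph
(the transductive formulation has no natural minibatch) — minimising mean
cross-entropy over the train-mask nodes only.  Defaults: lr 0.001, weight
decay 5e-4 added to every parameter's gradient (the coupled-L2 convention
of common Adam implementations), β₁ = 0.9, β₂ = 0.999, ε = 1e-8, and fixed
epoch budgets (300 for fold-CV-style runs, 1300 for the large-holdout
preset) with no early stopping or schedule.  Missing classes in the train
mask are a hard error: the loss would silently ignore an absent class.

Backward passes are hand-derived per layer (the GAT path propagates through
the segment softmax, the LeakyReLU scoring, and both input transforms) and
are checked against central finite differences at 1e-4 relative tolerance.
Forward/backward run in double precision.  Edge orderings, softmax
groupings and sparse scatter matrices are structure-only and cached per
graph.

### Evaluation and hyperparameter search

Two protocols: leave-one-fold-out over predefined folds (accuracy reported
as mean ± std; std is the **population** standard deviation, ddof = 0 — a
reporting convention recorded in every result), and a stratified random
80/20 holdout (per class, `round(count·0.2)` test nodes).  Whether a real
survey's split was site-blocked rather than stratified is unknowable from a
table alone; a grouped split can be emulated by supplying explicit masks.

The search over k ∈ [3, 15] and hidden ∈ [32, 256] (ranges covering the
published optima) uses random sampling by default.  Its objective is
accuracy on an inner validation split carved from training data only;
scoring on the test split is possible only through an explicit
`objective="test"` escape hatch, because the original tuning objective is
undocumented and the safe default must not leak.  Tuned configurations for
the two real benchmark settings ship as presets and are not search targets:
regenerating them would require the original audio and extractor weights.

## Synthetic data

The generator emulates the one statistical property the pipeline relies on:
embeddings of same-class recordings cluster, making the k-NN graph
homophilous.  Features are class-conditional isotropic Gaussians
(`noise_sd = 1`) whose means sit at scaled standard-simplex vertices, so
all pairwise mean distances equal `class_sep · noise_sd` and one knob spans
chance-level (`class_sep = 0`) to cleanly separated (`class_sep ≥ 8`)
regimes.  Class sizes follow largest-remainder apportionment of the
requested proportions (defaults balanced; a 20/21/59% preset mirrors a
strongly imbalanced three-habitat survey).  Folds are dealt round-robin
within each class, so fold class-proportions match global ones to within
one node; the holdout variant marks evenly spaced within-class positions as
test.  A single integer seed drives all randomness and identical seeds
reproduce tables bit-for-bit.

What the generator does **not** emulate: anisotropic or multi-modal class
structure, temporal correlation between recordings from one site or hour,
label noise, and within-recording segment structure beyond repeated ids.
Tests passing on these fixtures therefore demonstrate correctness of graph
construction, message passing, optimisation and protocol plumbing — not
field-level accuracy on real soundscapes, which depends on embedding
quality and habitat overlap.

## Problem sizes and numerical choices

Test and demonstration runs use a few hundred nodes (up to 600 for learning
checks, 500 for the exact brute-force k-NN comparison), sizes at which
clustered synthetic data is comfortably learnable in the standard 300-epoch
budget and the whole suite stays quick on one core.  Layer implementations
are required to match dense/naive oracle formulations within 1e-6
elementwise; attention rows sum to 1 within 1e-9; degenerate inputs
(isolated nodes, empty masks, k ≥ n, zero-norm vectors under cosine,
classes missing from a train mask) fail loudly rather than silently.

## Known limitations

- Exact O(n²) neighbour search: fine to tens of thousands of nodes,
  not millions.
- Two-layer architectures only; deeper stacks, edge weights/features and
  minibatch neighbour sampling are out of scope.
- Accuracy is the only scoring metric (a per-class confusion table is
  available as a diagnostic through the results object's predictions).
- CPU-only.
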