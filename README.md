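# soundgraph

Graph-based classification of audio recordings from deep embeddings.

## The problem

Passive acoustic monitoring and environmental-sound studies produce large
collections of recordings that need labelling — urban sound classes, or the
land cover (forest / savanna / pasture) of the site a recording came from.
A practical recipe is to summarise each recording with a fixed-length
embedding from a pre-trained audio network (VGGish-style 128-d, YAMNet-style
1024-d, PANNs-style 2048-d), and `soundgraph` takes it from there: instead of
classifying embeddings independently, it treats each recording as a node of
a **k-nearest-neighbour graph** built in embedding space and solves
**transductive node classification** with a graph neural network — test
recordings contribute their features and edges during training, only their
labels stay hidden.

## The models

All three GNNs are two-layer message-passing networks implemented from
scratch (NumPy forward passes, hand-derived backward passes validated by
finite differences), with ReLU between layers, dropout p = 0.5 on layer
inputs, and full-batch Adam (lr 10⁻³, weight decay 5·10⁻⁴) on masked
cross-entropy:

- **GCN** — symmetric degree-normalised propagation
  `H' = σ(D̃^(-1/2) Ã D̃^(-1/2) H W + b)` with Ã = A + I;
- **GraphSAGE** — mean neighbourhood aggregation with a separate self
  transform, `h'_u = σ(W·mean_{v∈N_u} h_v + B·h_u + b)` (no self-loop);
- **GAT** — attention-weighted aggregation
  `h'_u = σ(Σ_{v∈N_u∪{u}} α_uv W_r h_v)`, where per head
  `α_uv = softmax_v(aᵀ LeakyReLU₀.₂(W_l h_u + W_r h_v))`; 10 heads
  concatenated in the hidden layer, one head in the output layer.

A synthetic-table generator (class-conditional Gaussians with a single
separation knob, stratified folds or 80/20 holdout) makes the whole pipeline
testable without audio, and a hyperparameter search over k and hidden width
(random search, leakage-safe inner validation split) mirrors the tuning step
used on the real benchmarks.

## Worked example

```python
import soundgraph as sg

table = sg.generate_embeddings(
    sg.SyntheticSpec(n_nodes=300, d=32, n_classes=3, class_sep=8.0, seed=1)
)
res = sg.GNNNodeClassifier(table, arch="gat", k=6, n_hidden=16).fit(
    epochs=300, seed=1
)
print(res.summary())
```

prints

```
Graph Node Classifier Results
==========================================
Architecture                GAT
Nodes / features / classes  300 / 32 / 3
Graph                       k=6, euclidean, symmetric
Hidden width                16 x 10 heads
Trainable parameters        11,852
Epochs / lr / weight decay  300 / 0.001 / 0.0005
Final training loss         0.0021
Training accuracy           1.000
Held-out accuracy           1.000
```

The table simulates 300 recordings in 32 dimensions whose three classes sit
eight noise standard deviations apart — strongly clustered, like real
embeddings of acoustically distinct habitats.  The GAT classifies every
held-out node correctly; `res.probabilities` holds per-node class
probabilities and `res.loss_history` the training curve.  With
`class_sep=0` the same pipeline drops to the 1/3 chance line, confirming the
graph carries no label information beyond the features.

The same stages are scriptable from the shell:

```sh
soundgraph synth --n-nodes 300 --dim 32 --classes 3 --class-sep 8 --out table.csv
soundgraph build-graph --table table.csv --k 6 --out edges.tsv
soundgraph run --table table.csv --arch gat --k 6 --hidden 16 --out-dir results/
soundgraph cv  --table folds.csv --arch gcn --k 5 --hidden 55 --report cv.json
soundgraph hpo --table table.csv --arch gat --trials 20 --report hpo.json
```

Tuned (k, hidden) presets for the published benchmark settings live in
`soundgraph.presets`.

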