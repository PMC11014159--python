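"""Reading and writing embedding tables and edge lists.

The on-disk table format is delimited text (comma for ``.csv``, tab for
``.tsv``) with a header ``id,label,fold,f0..f{d-1}``; the ``fold`` column is
optional and may instead hold the strings ``train``/``test`` for a holdout
split.  Labels are re-encoded to dense integers in lexicographic order of the
class names; the original names are kept on the table so reports can show
them.  Node indexing is 0-based internally; fold numbering is 1-based, the
convention the benchmark datasets use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING_LABEL = -1  # test rows may carry no label; they are only scored


@dataclass
class EmbeddingTable:
    """Node payload of the audio graph: one embedding vector per recording.

    Attributes
    ----------
    node_ids : ndarray of str
        Ordered unique recording identifiers.
    features : ndarray, shape (n_nodes, d)
        One fixed-length embedding per recording (the initial node features).
    labels : ndarray of int, shape (n_nodes,)
        Dense class codes in ``[0, n_classes)``; ``MISSING_LABEL`` for test
        rows whose label is withheld.
    split : ndarray, shape (n_nodes,)
        Either integer fold indices forming a contiguous 1-based range, or
        the strings ``"train"``/``"test"``.
    class_names : list of str
        Decodes dense labels back to the original names.
    """

    node_ids: np.ndarray
    features: np.ndarray
    labels: np.ndarray
    split: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids)
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.split = np.asarray(self.split)
        n = len(self.node_ids)
        if self.features.ndim != 2 or self.features.shape[0] != n:
            raise ValueError(
                f"features must be a ({n}, d) matrix, got {self.features.shape}"
            )
        if self.features.shape[1] < 1:
            raise ValueError("feature dimension must be positive")
        if not np.isfinite(self.features).all():
            bad = np.argwhere(~np.isfinite(self.features))[0]
            raise ValueError(
                f"non-finite feature at row {bad[0]}, column f{bad[1]}"
            )
        if len(self.labels) != n or len(self.split) != n:
            raise ValueError("labels and split must cover every node")
        if len(np.unique(self.node_ids)) != n:
            raise ValueError("node ids must be unique")
        present = self.labels[self.labels != MISSING_LABEL]
        if present.size and (present.min() < 0 or present.max() >= self.n_classes):
            raise ValueError("labels must be dense integers in [0, n_classes)")
        if self.has_folds:
            folds = np.unique(self.fold_indices)
            if not np.array_equal(folds, np.arange(folds.min(), folds.max() + 1)):
                raise ValueError("fold indices must form a contiguous range")

    # -- derived views ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        if self.class_names:
            return len(self.class_names)
        present = self.labels[self.labels != MISSING_LABEL]
        return int(present.max()) + 1 if present.size else 0

    @property
    def has_folds(self) -> bool:
        return self.split.dtype.kind in "iu"

    @property
    def fold_indices(self) -> np.ndarray:
        return self.split.astype(np.int64)

    def train_mask_for_fold(self, fold: int) -> np.ndarray:
        """Boolean mask of nodes *outside* the given fold."""
        return self.fold_indices != fold

    def holdout_masks(self) -> tuple[np.ndarray, np.ndarray]:
        train = self.split == "train"
        test = self.split == "test"
        if not train.any() or not test.any():
            raise ValueError("split must contain both 'train' and 'test' rows")
        return train, test


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def load_embedding_table(
    path: str | Path, schema: dict[str, str] | None = None
) -> EmbeddingTable:
    """Load an embedding table from delimited text.

    ``schema`` optionally remaps column roles, e.g.
    ``{"id": "clip", "label": "class", "fold": "cv_fold"}``.  Feature columns
    are every remaining column, in file order.  A missing or non-numeric
    feature value is a hard error naming the cell.  Rows in the ``test``
    portion of a holdout split may leave the label empty.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    roles = {"id": "id", "label": "label", "fold": "fold"}
    if schema:
        roles.update(schema)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={roles["id"]: str})
    for role in ("id", "label"):
        if roles[role] not in df.columns:
            raise ValueError(f"missing required column '{roles[role]}'")
    feat_cols = [
        c for c in df.columns if c not in (roles["id"], roles["label"], roles["fold"])
    ]
    if not feat_cols:
        raise ValueError("no feature columns found")
    feats = df[feat_cols].apply(pd.to_numeric, errors="coerce").to_numpy(np.float64)
    if not np.isfinite(feats).all():
        r, c = np.argwhere(~np.isfinite(feats))[0]
        raise ValueError(
            f"missing or non-numeric feature at row {r}, column '{feat_cols[c]}'"
        )

    if roles["fold"] in df.columns:
        raw_split = df[roles["fold"]]
        if raw_split.map(lambda s: str(s).lstrip("-").isdigit()).all():
            split = raw_split.astype(np.int64).to_numpy()
        else:
            split = raw_split.to_numpy(dtype="U8")
    else:
        split = np.full(len(df), "train")

    raw_labels = df[roles["label"]]
    is_test = (
        (split == "test") if split.dtype.kind in "US" else np.zeros(len(df), bool)
    )
    absent = raw_labels.isna().to_numpy()
    if (absent & ~is_test).any():
        r = int(np.argwhere(absent & ~is_test)[0][0])
        raise ValueError(f"missing label at row {r} outside the test split")
    names = sorted(raw_labels.dropna().astype(str).unique())
    code = {name: i for i, name in enumerate(names)}
    labels = np.array(
        [MISSING_LABEL if a else code[str(v)] for v, a in zip(raw_labels, absent)],
        dtype=np.int64,
    )
    return EmbeddingTable(
        node_ids=df[roles["id"]].to_numpy(),
        features=feats,
        labels=labels,
        split=split,
        class_names=names,
    )


def write_embedding_table(table: EmbeddingTable, path: str | Path) -> None:
    """Write a table in the canonical ``id,label,fold,f0..`` layout."""
    path = Path(path)
    names = table.class_names or [str(i) for i in range(table.n_classes)]
    label_col = [
        "" if int(l) == MISSING_LABEL else names[int(l)] for l in table.labels
    ]
    df = pd.DataFrame({"id": table.node_ids, "label": label_col, "fold": table.split})
    for j in range(table.d):
        df[f"f{j}"] = table.features[:, j]
    df.to_csv(path, sep=_sep_for(path), index=False)


def average_segments(segments: np.ndarray) -> np.ndarray:
    """Collapse a (n_segments, d) block of per-segment embeddings to one
    clip-level vector by the column-wise arithmetic mean.

    Segment-level extractors emit one vector per ~1 s window; a recording's
    node feature is the mean over its windows.
    """
    segments = np.asarray(segments, dtype=np.float64)
    if segments.ndim != 2 or segments.shape[0] < 1:
        raise ValueError("segments must be a non-empty (n_segments, d) matrix")
    return segments.mean(axis=0)


def collapse_segments(
    ids: np.ndarray, segments: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Average rows of ``segments`` sharing an id, preserving first-seen order.

    Returns (unique_ids, clip_features).  Tables whose rows are already
    clip-level pass through unchanged.
    """
    ids = np.asarray(ids)
    segments = np.asarray(segments, dtype=np.float64)
    uniq, first = np.unique(ids, return_index=True)
    order = np.argsort(first)
    uniq = uniq[order]
    out = np.vstack([average_segments(segments[ids == u]) for u in uniq])
    return uniq, out


def write_edge_list(graph, path: str | Path) -> None:
    """Write edges as tab-separated ``source<TAB>target`` pairs, 0-based,
    sorted by (source, target)."""
    edges = np.asarray(graph.edges, dtype=np.int64)
    if edges.size and (edges.min() < 0 or edges.max() >= graph.n_nodes):
        raise ValueError("edge indices out of range")
    if edges.size:
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        edges = edges[order]
    with open(path, "w", encoding="utf-8") as fh:
        for s, t in edges:
            fh.write(f"{s}\t{t}\n")


def read_edge_list(path: str | Path, n_nodes: int):
    """Read an edge-list TSV back into a :class:`~soundgraph.graph.KnnGraph`."""
    from .graph import KnnGraph

    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                s, t = line.split("\t")
                rows.append((int(s), int(t)))
    edges = (
        np.array(rows, dtype=np.int64) if rows else np.empty((0, 2), dtype=np.int64)
    )
    return KnnGraph(n_nodes=n_nodes, edges=edges, k=0, metric="unknown")
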