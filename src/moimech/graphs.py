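"""Shared in-memory graph containers.

:class:`AttributedGraph` is the common currency between modules: the
interaction network after node annotation, and each residue-level protein
graph, are both undirected graphs whose nodes carry numeric feature vectors.
:class:`ResidueGraph` adds 3-D coordinates and typed edge sets (peptide,
disulfide, hydrogen bond, ...) on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EDGE_TYPES = (
    "peptide",
    "disulfide",
    "hbond",
    "ionic",
    "aromatic",
    "aromatic_sulfur",
    "cation_pi",
    "long_range",
)


def _normalize_edges(edges, n: int) -> list[tuple[int, int]]:
    out = set()
    for i, j in edges:
        i, j = int(i), int(j)
        if i == j:
            raise ValueError(f"self-loop on node index {i}")
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"edge ({i},{j}) outside node range [0,{n})")
        out.add((min(i, j), max(i, j)))
    return sorted(out)


@dataclass
class AttributedGraph:
    """Undirected graph with per-node feature vectors.

    Edges are stored once as index pairs ``(i, j)`` with ``i < j``; no
    self-loops (message-passing layers insert their own where the layer
    definition calls for one).
    """

    node_ids: list[str]
    edges: list[tuple[int, int]]
    X: np.ndarray | None = None
    feature_names: list[str] | None = None
    y: np.ndarray | None = None
    label_names: list[str] | None = None

    def __post_init__(self):
        self.edges = _normalize_edges(self.edges, len(self.node_ids))
        if self.X is not None:
            self.X = np.asarray(self.X, dtype=np.float64)
            if self.X.shape[0] != len(self.node_ids):
                raise ValueError("feature matrix row count != node count")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def adjacency(self, self_loops: bool = False) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix."""
        n = self.n_nodes
        A = np.zeros((n, n))
        for i, j in self.edges:
            A[i, j] = A[j, i] = 1.0
        if self_loops:
            np.fill_diagonal(A, 1.0)
        return A

    def permuted(self, perm: np.ndarray) -> "AttributedGraph":
        """Relabel nodes: new node k is old node perm[k]."""
        perm = np.asarray(perm)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        return AttributedGraph(
            node_ids=[self.node_ids[p] for p in perm],
            edges=[(inv[i], inv[j]) for i, j in self.edges],
            X=None if self.X is None else self.X[perm],
            feature_names=self.feature_names,
            y=self.y[perm] if self.y is not None and self.y.shape[0] == self.n_nodes else self.y,
            label_names=self.label_names,
        )


@dataclass
class ResidueGraph(AttributedGraph):
    """Residue-level protein graph with typed edges and coordinates.

    ``typed_edges`` maps an edge-type tag to its set of index pairs; the
    untyped ``edges`` list (consumed by the GNN) is their flattened union.
    ``residue_index`` holds the 1-based sequence numbers from the structure
    file, ``residue_names`` the 3-letter codes, and ``coords`` one
    representative (CA) coordinate per residue.
    """

    residue_index: list[int] = field(default_factory=list)
    residue_names: list[str] = field(default_factory=list)
    coords: np.ndarray | None = None
    typed_edges: dict[str, set[tuple[int, int]]] = field(default_factory=dict)
    protein_id: str = ""

    def __post_init__(self):
        super().__post_init__()
        for tag, pairs in self.typed_edges.items():
            if tag not in EDGE_TYPES:
                raise ValueError(f"unknown edge type {tag!r}")
            self.typed_edges[tag] = {(min(i, j), max(i, j)) for i, j in pairs}
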