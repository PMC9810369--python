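"""Core data containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SeriesMatrix", "CorrelationMatrix", "BinaryGraph"]


def _default_labels(n: int) -> list[str]:
    return [str(i) for i in range(n)]


@dataclass
class SeriesMatrix:
    """Node x timepoint real-valued series."""

    values: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D node x timepoint matrix")
        n, t = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 nodes, got {n}")
        if t < 3:
            raise ValueError(f"need at least 3 timepoints, got {t}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series contains missing or non-finite values")
        if not self.node_labels:
            self.node_labels = _default_labels(n)
        if len(self.node_labels) != n:
            raise ValueError("node_labels length does not match row count")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of pairwise Pearson coefficients with unit diagonal."""

    rho: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        r = self.rho
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("rho must be square")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValueError("rho must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-10):
            raise ValueError("rho must have unit diagonal")
        if np.any(np.abs(r) > 1.0 + 1e-10):
            raise ValueError("correlation entries must lie in [-1, 1]")
        if not self.node_labels:
            self.node_labels = _default_labels(r.shape[0])
        if len(self.node_labels) != r.shape[0]:
            raise ValueError("node_labels length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.rho.shape[0]


@dataclass
class BinaryGraph:
    """Undirected unweighted simple graph with threshold provenance.

    Backed by a dense boolean adjacency matrix (node counts in this pipeline
    are a few hundred at most).  ``lcc_mask`` marks the largest connected
    component, ties broken by the component containing the smallest node id.
    """

    adj: np.ndarray
    node_labels: list[str] = field(default_factory=list)
    threshold: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adj)
        if a.dtype != bool:
            a = a.astype(bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric (undirected graph)")
        if np.any(np.diag(a)):
            raise ValueError("self-loops are not allowed")
        self.adj = a
        if not self.node_labels:
            self.node_labels = _default_labels(a.shape[0])
        if len(self.node_labels) != a.shape[0]:
            raise ValueError("node_labels length does not match adjacency size")

    @property
    def n_nodes(self) -> int:
        return self.adj.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adj.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adj.sum(axis=1).astype(int)

    @property
    def lcc_mask(self) -> np.ndarray:
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        n_comp, labels = connected_components(csr_matrix(self.adj), directed=False)
        sizes = np.bincount(labels, minlength=n_comp)
        best = np.max(sizes)
        # tie-break: component containing the smallest node id among ties
        tied = np.flatnonzero(sizes == best)
        mins = [np.flatnonzero(labels == c)[0] for c in tied]
        chosen = tied[int(np.argmin(mins))]
        return labels == chosen

    def edge_list(self) -> np.ndarray:
        """(m, 2) array of edges with i < j."""
        i, j = np.nonzero(np.triu(self.adj, k=1))
        return np.column_stack([i, j])

    def is_connected(self) -> bool:
        return bool(self.lcc_mask.all())

    def to_networkx(self):
        import networkx as nx

        g = nx.from_numpy_array(self.adj.astype(int))
        for i, lab in enumerate(self.node_labels):
            g.nodes[i]["label"] = lab
        return g
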