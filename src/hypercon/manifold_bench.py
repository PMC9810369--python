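"""Embedding binary graphs into constant-curvature spaces by Riemannian SGD.

Spaces are kept at unit curvature (Euclidean R^d, unit sphere S^d, unit
hyperboloid H^d); a jointly-optimized global scale ``s`` absorbs curvature
magnitude.  The loss per node pair is ``((d_V / (s * d_U))**2 - 1)**2`` with
``d_U`` the graph (hop-count) distance.  Fidelity is scored by average
distortion and mean average precision.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .types import BinaryGraph

__all__ = [
    "ManifoldSpec",
    "EmbeddingResult",
    "graph_metric",
    "space_distance",
    "rsgd_embed",
    "distortion",
    "mean_average_precision",
]

CONSTRAINT_TOL = 1e-6


@dataclass(frozen=True)
class ManifoldSpec:
    """Target model space: curvature sign and dimension."""

    curvature_sign: str
    dimension: int

    def __post_init__(self) -> None:
        if self.curvature_sign not in ("negative", "zero", "positive"):
            raise ValueError(f"unknown curvature sign {self.curvature_sign!r}")
        if self.dimension < 1:
            raise ValueError("dimension must be at least 1")

    @classmethod
    def parse(cls, tag: str) -> "ManifoldSpec":
        """Parse compact tags like 'H2', 'E10', 'S1'."""
        m = re.fullmatch(r"([EHS])(\d+)", tag.strip().upper())
        if not m:
            raise ValueError(f"cannot parse space tag {tag!r} (expected e.g. H2)")
        sign = {"E": "zero", "H": "negative", "S": "positive"}[m.group(1)]
        return cls(curvature_sign=sign, dimension=int(m.group(2)))

    @property
    def ambient_dim(self) -> int:
        return self.dimension if self.curvature_sign == "zero" else self.dimension + 1

    @property
    def tag(self) -> str:
        letter = {"zero": "E", "negative": "H", "positive": "S"}[self.curvature_sign]
        return f"{letter}{self.dimension}"


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray
    space: ManifoldSpec
    loss_trace: np.ndarray
    converged: bool
    d_avg: float
    map_score: float
    scale: float
    epochs_run: int = 0
    node_labels: list[str] = field(default_factory=list)


def graph_metric(g: BinaryGraph) -> np.ndarray:
    """All-pairs shortest-path hop counts of a connected graph."""
    if not g.is_connected():
        raise ValueError(
            "graph is disconnected; extract the largest connected component first"
        )
    d = shortest_path(csr_matrix(g.adj.astype(int)), method="D", unweighted=True)
    return d.astype(float)


def _check_on_manifold(p: np.ndarray, m: ManifoldSpec) -> None:
    if m.curvature_sign == "zero":
        return
    if m.curvature_sign == "positive":
        residual = np.abs(np.sum(p * p, axis=-1) - 1.0)
    else:
        residual = np.abs(_minkowski(p, p) + 1.0)
    if np.any(residual > CONSTRAINT_TOL):
        raise ValueError(
            f"point(s) off the {m.tag} model space (max residual {residual.max():.2e})"
        )


def _minkowski(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    return -p[..., 0] * q[..., 0] + np.sum(p[..., 1:] * q[..., 1:], axis=-1)


def space_distance(p: np.ndarray, q: np.ndarray, m: ManifoldSpec) -> np.ndarray:
    """Geodesic distance between points of the model space of ``m``."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    _check_on_manifold(p, m)
    _check_on_manifold(q, m)
    if m.curvature_sign == "zero":
        return np.linalg.norm(p - q, axis=-1)
    if m.curvature_sign == "positive":
        return np.arccos(np.clip(np.sum(p * q, axis=-1), -1.0, 1.0))
    return np.arccosh(np.maximum(-_minkowski(p, q), 1.0))


def _pairwise(points: np.ndarray, m: ManifoldSpec) -> np.ndarray:
    if m.curvature_sign == "zero":
        diff = points[:, None, :] - points[None, :, :]
        d = np.linalg.norm(diff, axis=-1)
    elif m.curvature_sign == "positive":
        d = np.arccos(np.clip(points @ points.T, -1.0, 1.0))
    else:
        gram = -np.outer(points[:, 0], points[:, 0]) + points[:, 1:] @ points[:, 1:].T
        d = np.arccosh(np.maximum(-gram, 1.0))
    np.fill_diagonal(d, 0.0)
    return d


def _project_constraint(points: np.ndarray, m: ManifoldSpec) -> np.ndarray:
    """Snap points back onto the model space (kills numerical drift)."""
    if m.curvature_sign == "zero":
        return points
    if m.curvature_sign == "positive":
        return points / np.linalg.norm(points, axis=1, keepdims=True)
    out = points.copy()
    out[:, 0] = np.sqrt(1.0 + np.sum(out[:, 1:] ** 2, axis=1))
    return out


def _init_points(n: int, m: ManifoldSpec, rng: np.random.Generator) -> np.ndarray:
    noise = 1e-3 * rng.standard_normal((n, m.ambient_dim))
    if m.curvature_sign == "zero":
        return noise
    if m.curvature_sign == "positive":
        pts = noise
        pts[:, -1] += 1.0  # cluster near a pole
        return _project_constraint(pts, m)
    pts = noise
    pts[:, 0] = 0.0
    return _project_constraint(pts, m)


def _distance_and_grads(
    points: np.ndarray, pairs: np.ndarray, m: ManifoldSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair distances and ambient Euclidean gradients d(dist)/d(endpoint)."""
    p = points[pairs[:, 0]]
    q = points[pairs[:, 1]]
    if m.curvature_sign == "zero":
        diff = p - q
        d = np.linalg.norm(diff, axis=1)
        safe = np.maximum(d, 1e-12)[:, None]
        gp = diff / safe
        return d, gp, -gp
    if m.curvature_sign == "positive":
        dot = np.clip(np.sum(p * q, axis=1), -1.0, 1.0)
        d = np.arccos(dot)
        denom = np.maximum(np.sqrt(1.0 - dot**2), 1e-9)[:, None]
        return d, -q / denom, -p / denom
    c = np.maximum(-_minkowski(p, q), 1.0)
    d = np.arccosh(c)
    denom = np.maximum(np.sqrt(c**2 - 1.0), 1e-9)[:, None]
    gq_mink = np.concatenate([q[:, :1], -q[:, 1:]], axis=1)  # -G q
    gp_mink = np.concatenate([p[:, :1], -p[:, 1:]], axis=1)
    return d, gq_mink / denom, gp_mink / denom


MAX_STEP = 1.0  # cap on per-node step length, keeps exp-map retractions finite


def _riemannian_step(
    points: np.ndarray, grads: np.ndarray, lr: float, m: ManifoldSpec
) -> np.ndarray:
    """Tangent-project the ambient gradient, retract by the exponential map."""
    if m.curvature_sign == "zero":
        step = -lr * grads
        norm = np.linalg.norm(step, axis=1, keepdims=True)
        step *= np.minimum(1.0, MAX_STEP / np.maximum(norm, 1e-15))
        return points + step
    if m.curvature_sign == "positive":
        tang = grads - np.sum(grads * points, axis=1, keepdims=True) * points
        step = -lr * tang
        norm = np.linalg.norm(step, axis=1, keepdims=True)
        scale_down = np.minimum(1.0, MAX_STEP / np.maximum(norm, 1e-15))
        step *= scale_down
        norm = norm * scale_down
        small = norm < 1e-15
        direction = np.where(small, 0.0, step / np.maximum(norm, 1e-15))
        out = np.cos(norm) * points + np.sin(norm) * direction
        return _project_constraint(out, m)
    # hyperboloid: raise index with G, project to tangent, exp-map retract
    h = np.concatenate([-grads[:, :1], grads[:, 1:]], axis=1)  # G * grad
    inner = _minkowski(points, h)[:, None]
    tang = h + inner * points
    step = -lr * tang
    sq = np.maximum(_minkowski(step, step), 0.0)[:, None]
    norm = np.sqrt(sq)
    scale_down = np.minimum(1.0, MAX_STEP / np.maximum(norm, 1e-15))
    step *= scale_down
    norm = norm * scale_down
    small = norm < 1e-15
    direction = np.where(small, 0.0, step / np.maximum(norm, 1e-15))
    out = np.cosh(norm) * points + np.sinh(norm) * direction
    return _project_constraint(out, m)


def rsgd_embed(
    g: BinaryGraph,
    m: ManifoldSpec,
    epochs: int = 1500,
    lr: float = 0.02,
    batch: int = 0,
    seed: int = 0,
    tol: float = 1e-4,
) -> EmbeddingResult:
    """Minimize the scaled-distortion loss by Riemannian (S)GD.

    ``batch = 0`` uses all node pairs per step; otherwise pairs are shuffled
    into minibatches each epoch.  The global scale ``s`` is re-solved in
    closed form every epoch.  Convergence means the relative loss change over
    the last 10 epochs fell below ``tol``.
    """
    if epochs < 1:
        raise ValueError("epochs must be at least 1")
    d_graph = graph_metric(g)
    n = g.n_nodes
    iu = np.triu_indices(n, k=1)
    pairs = np.column_stack(iu)
    g_u = d_graph[iu]
    rng = np.random.default_rng(seed)
    points = _init_points(n, m, rng)
    scale = 1.0
    trace = np.empty(epochs)
    epochs_run = epochs
    converged = False

    for epoch in range(epochs):
        d_all = _pairwise(points, m)[iu]
        x = d_all / g_u
        x2 = np.sum(x**2)
        x4 = np.sum(x**4)
        if x4 > 0:
            scale = float(np.sqrt(x4 / np.maximum(x2, 1e-300)))
        scale = max(scale, 1e-9)
        if m.curvature_sign == "zero":
            # flat space: fold the optimal scale into the coordinates so the
            # configuration cannot drift to sizes where gradients vanish
            points = points / scale
            d_all = d_all / scale
            scale = 1.0
        q = (d_all / (scale * g_u)) ** 2
        trace[epoch] = float(np.mean((q - 1.0) ** 2))

        if epoch >= 10:
            prev = trace[epoch - 10]
            flat = prev > 0 and abs(prev - trace[epoch]) / prev < tol
            if flat or trace[epoch] < 1e-16:
                converged = True
                epochs_run = epoch + 1
                break

        if batch and batch < pairs.shape[0]:
            order = rng.permutation(pairs.shape[0])
            chunks = np.array_split(order, int(np.ceil(order.size / batch)))
        else:
            chunks = [np.arange(pairs.shape[0])]
        step_lr = lr / (1.0 + epoch / 500.0)
        for chunk in chunks:
            sub = pairs[chunk]
            d_c, gp, gq = _distance_and_grads(points, sub, m)
            sg = scale * g_u[chunk]
            qq = (d_c / sg) ** 2
            dldd = 4.0 * d_c * (qq - 1.0) / sg**2
            grads = np.zeros_like(points)
            np.add.at(grads, sub[:, 0], dldd[:, None] * gp)
            np.add.at(grads, sub[:, 1], dldd[:, None] * gq)
            counts = np.bincount(sub.ravel(), minlength=n).astype(float)
            grads /= np.maximum(counts, 1.0)[:, None]
            points = _riemannian_step(points, grads, step_lr, m)

    trace = trace[:epochs_run]
    d_final = _pairwise(points, m)
    d_avg = distortion(d_final / scale, d_graph)
    map_score = mean_average_precision(g, d_final)
    return EmbeddingResult(
        coordinates=points,
        space=m,
        loss_trace=trace,
        converged=converged,
        d_avg=d_avg,
        map_score=map_score,
        scale=scale,
        epochs_run=epochs_run,
        node_labels=list(g.node_labels),
    )


def distortion(embedded: np.ndarray, graph: np.ndarray) -> float:
    """Mean over unordered pairs of |d_V - d_U| / d_U (0 is perfect)."""
    embedded = np.asarray(embedded, dtype=float)
    graph = np.asarray(graph, dtype=float)
    if embedded.shape != graph.shape:
        raise ValueError("distance tables must share one index set")
    iu = np.triu_indices(graph.shape[0], k=1)
    g_u = graph[iu]
    if np.any(g_u <= 0):
        raise ValueError("graph distances must be positive off the diagonal")
    return float(np.mean(np.abs(embedded[iu] - g_u) / g_u))


def mean_average_precision(g: BinaryGraph, embedded: np.ndarray) -> float:
    """Rank-based retrieval quality of graph neighbors from embedded distances.

    For node ``a`` and each neighbor ``b``, the retrieval set is the smallest
    ball of nearest-to-``a`` nodes containing ``b``; its precision is the
    fraction of that ball made of true neighbors.  Ties in distance are
    broken deterministically by node id.
    """
    embedded = np.asarray(embedded, dtype=float)
    n = g.n_nodes
    if embedded.shape != (n, n):
        raise ValueError("embedded distance table does not match the graph")
    degrees = g.degrees
    if np.any(degrees == 0):
        bad = np.flatnonzero(degrees == 0)
        raise ValueError(
            f"isolated node(s) {bad.tolist()}; extract the largest component first"
        )
    ap = np.empty(n)
    ids = np.arange(n)
    for a in range(n):
        others = ids[ids != a]
        # deterministic tie-break: sort by (distance, node id)
        order = others[np.lexsort((others, embedded[a, others]))]
        is_nbr = g.adj[a, order]
        ranks = np.flatnonzero(is_nbr) + 1  # 1-based rank of each neighbor
        cum_hits = np.arange(1, ranks.size + 1)
        ap[a] = np.mean(cum_hits / ranks)
    return float(np.mean(ap))
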