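"""Synthetic inputs with the statistical structure the pipeline assumes.

Provides block-correlated Gaussian time series (stand-ins for region-averaged
signal), geometric circle-model networks with known hidden variables, control
cohorts of repeated draws, and topological anomaly injection for
detector-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _s1model
from .types import BinaryGraph, SeriesMatrix

__all__ = [
    "GroundTruthS1",
    "SyntheticCohort",
    "make_powerlaw_ground_truth",
    "gen_block_timeseries",
    "gen_s1_network",
    "gen_control_cohort",
    "inject_anomaly",
]


@dataclass
class GroundTruthS1:
    """Hidden variables of the circle model: per-node (kappa, theta), beta, mu."""

    kappa: np.ndarray
    theta: np.ndarray
    beta: float
    mu: float

    def __post_init__(self) -> None:
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float) % (2.0 * np.pi)
        if self.kappa.shape != self.theta.shape or self.kappa.ndim != 1:
            raise ValueError("kappa and theta must be 1-D arrays of equal length")
        if np.any(self.kappa <= 0):
            raise ValueError("all hidden degrees must be positive")
        if self.beta <= 1:
            raise ValueError(f"beta must exceed 1 (clustered regime), got {self.beta}")
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")

    @property
    def n_nodes(self) -> int:
        return self.kappa.size

    def connection_probabilities(self) -> np.ndarray:
        return _s1model.connection_prob_matrix(
            self.kappa, self.theta, self.beta, self.mu
        )

    def hyperbolic_distances(self) -> np.ndarray:
        """Ground-truth disc distances under the standard change of variables."""
        from .s1h2 import disc_distance_matrix, to_disc

        disc = to_disc(self.kappa, self.theta, self.beta, mu=self.mu)
        return disc_distance_matrix(disc)


@dataclass
class SyntheticCohort:
    subjects: list[BinaryGraph]
    ground_truth: GroundTruthS1
    perturbation_log: list[tuple[int, tuple[int, int], str]] = field(
        default_factory=list
    )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def __post_init__(self) -> None:
        n = {s.n_nodes for s in self.subjects}
        if len(n) > 1:
            raise ValueError("all subjects must share one node set")
        for _, (i, j), _ in self.perturbation_log:
            m = self.subjects[0].n_nodes
            if not (0 <= i < m and 0 <= j < m):
                raise ValueError(f"perturbation log refers to unknown pair ({i}, {j})")


def make_powerlaw_ground_truth(
    n_nodes: int,
    gamma: float = 2.7,
    mean_degree: float = 10.0,
    beta: float = 2.5,
    seed: int = 0,
) -> GroundTruthS1:
    """Ground truth with truncated-Pareto hidden degrees and uniform angles."""
    rng = np.random.default_rng(seed)
    kappa = _s1model.sample_powerlaw_kappa(n_nodes, gamma, mean_degree, rng)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n_nodes)
    mu = _s1model.mu_from_beta(beta, mean_degree)
    return GroundTruthS1(kappa=kappa, theta=theta, beta=beta, mu=mu)


def gen_block_timeseries(
    n_nodes: int,
    n_timepoints: int,
    block_sizes: list[int],
    within_r: float,
    between_r: float = 0.0,
    seed: int = 0,
) -> SeriesMatrix:
    """Zero-mean multivariate normal series with block correlation structure.

    The target correlation matrix has ``within_r`` inside diagonal blocks and
    ``between_r`` elsewhere; it must be positive semi-definite.
    """
    if sum(block_sizes) != n_nodes:
        raise ValueError(
            f"block sizes sum to {sum(block_sizes)}, expected n_nodes={n_nodes}"
        )
    if not -1.0 < between_r <= within_r <= 1.0:
        raise ValueError("need -1 < between_r <= within_r <= 1")
    target = np.full((n_nodes, n_nodes), float(between_r))
    pos = 0
    for size in block_sizes:
        target[pos : pos + size, pos : pos + size] = within_r
        pos += size
    np.fill_diagonal(target, 1.0)
    eigvals, eigvecs = np.linalg.eigh(target)
    if eigvals.min() < -1e-10:
        raise ValueError(
            "block correlation target is not positive semi-definite "
            f"(smallest eigenvalue {eigvals.min():.3e})"
        )
    rng = np.random.default_rng(seed)
    root = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
    values = root @ rng.standard_normal((n_nodes, n_timepoints))
    return SeriesMatrix(values=values)


def gen_s1_network(gt: GroundTruthS1, seed: int = 0) -> BinaryGraph:
    """One Bernoulli draw of the circle-model graph at the given ground truth."""
    if gt.n_nodes < 10:
        raise ValueError("need at least 10 nodes")
    rng = np.random.default_rng(seed)
    p = gt.connection_probabilities()
    n = gt.n_nodes
    u = rng.random((n, n))
    upper = np.triu(u < p, k=1)
    adj = upper | upper.T
    return BinaryGraph(adj=adj)


def gen_control_cohort(
    gt: GroundTruthS1,
    n_subjects: int,
    edge_noise: float = 0.0,
    seed: int = 0,
) -> SyntheticCohort:
    """Independent draws from one ground truth, plus optional edge flips."""
    if not 0.0 <= edge_noise < 0.5:
        raise ValueError(f"edge_noise must lie in [0, 0.5), got {edge_noise}")
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    root = np.random.default_rng(seed)
    subjects = []
    for _ in range(n_subjects):
        # both seeds drawn unconditionally so the noise-free cohort at the
        # same seed shares its base draws with a noisy one
        draw_seed = int(root.integers(0, 2**63 - 1))
        flip_seed = int(root.integers(0, 2**63 - 1))
        g = gen_s1_network(gt, seed=draw_seed)
        if edge_noise > 0.0:
            flip_rng = np.random.default_rng(flip_seed)
            n = g.n_nodes
            flips = np.triu(flip_rng.random((n, n)) < edge_noise, k=1)
            adj = g.adj ^ (flips | flips.T)
            g = BinaryGraph(adj=adj)
        subjects.append(g)
    return SyntheticCohort(subjects=subjects, ground_truth=gt)


def inject_anomaly(
    cohort: SyntheticCohort,
    subject: int,
    pairs: list[tuple[int, int]],
    mode: str,
    seed: int = 0,
) -> SyntheticCohort:
    """Topologically perturb one subject so listed pairs become anomalous.

    ``lengthen`` disconnects each listed pair and rewires the cross-edges
    between their neighborhoods to random distant nodes (degree-preserving
    where possible), so the pair's graph neighborhoods decouple.  ``shorten``
    connects the pair and links each endpoint to the other's neighbors.
    Returns a new cohort; the input is untouched.
    """
    if mode not in ("lengthen", "shorten"):
        raise ValueError(f"mode must be 'lengthen' or 'shorten', got {mode!r}")
    if not 0 <= subject < cohort.n_subjects:
        raise KeyError(f"unknown subject index {subject}")
    n = cohort.subjects[0].n_nodes
    for i, j in pairs:
        if not (0 <= i < n and 0 <= j < n) or i == j:
            raise KeyError(f"unknown or degenerate node pair ({i}, {j})")

    rng = np.random.default_rng(seed)
    adj = cohort.subjects[subject].adj.copy()
    log = list(cohort.perturbation_log)
    for i, j in pairs:
        if mode == "lengthen":
            _lengthen_pair(adj, i, j, rng)
        else:
            _shorten_pair(adj, i, j)
        log.append((subject, (int(i), int(j)), mode))

    subjects = list(cohort.subjects)
    subjects[subject] = BinaryGraph(
        adj=adj, node_labels=list(cohort.subjects[subject].node_labels)
    )
    return SyntheticCohort(
        subjects=subjects, ground_truth=cohort.ground_truth, perturbation_log=log
    )


def _lengthen_pair(adj: np.ndarray, i: int, j: int, rng: np.random.Generator) -> None:
    """Disconnect (i, j) and relocate i's neighborhood away from j.

    An anchor node among the topologically most distant from ``j`` (top 5% of
    hop distances) is drawn, and every remaining edge of ``i`` is rewired into
    the anchor's neighborhood (degree-preserving while free slots exist).
    Coherent relocation — rather than scattering edges uniformly — is what
    makes the pair's inferred distance move decisively.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import shortest_path

    adj[i, j] = adj[j, i] = False
    hops = shortest_path(csr_matrix(adj.astype(int)), unweighted=True,
                         indices=j)
    reachable = np.isfinite(hops) & (hops > 0)
    if not reachable.any():
        return
    cutoff = np.percentile(hops[reachable], 95)
    anchor = int(rng.choice(np.flatnonzero(reachable & (hops >= cutoff))))
    targets = list(np.flatnonzero(adj[anchor])) + [anchor]
    for u in np.flatnonzero(adj[i]):
        if u == j:
            continue
        adj[i, u] = adj[u, i] = False
        free = [w for w in targets if w != i and not adj[i, w]]
        if free:
            w = int(rng.choice(free))
            adj[i, w] = adj[w, i] = True


def _shorten_pair(adj: np.ndarray, i: int, j: int) -> None:
    """Connect the pair, each endpoint to the other's neighbors, and the
    neighborhoods to each other."""
    nbr_i = np.flatnonzero(adj[i])
    nbr_j = np.flatnonzero(adj[j])
    adj[i, j] = adj[j, i] = True
    for b in nbr_j:
        if b != i:
            adj[i, b] = adj[b, i] = True
    for b in nbr_i:
        if b != j:
            adj[j, b] = adj[b, j] = True
    for a in nbr_i:
        for b in nbr_j:
            if a != b:
                adj[a, b] = adj[b, a] = True
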