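"""Maximum-likelihood embedding of binary graphs onto the hyperbolic disc.

Inference proceeds in three stages: the clustering strength ``beta`` is found
by matching the mean local clustering coefficient of synthetic circle-model
draws to the observed one; hidden degrees ``kappa`` are fit so mean-field
expected degrees reproduce observed degrees; angular coordinates are found by
spectral initialization followed by per-node likelihood sweeps.  The
``(kappa, theta)`` representation maps to disc polar coordinates via
``r_i = R_disc - 2 ln(kappa_i / kappa_min)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import _s1model
from .types import BinaryGraph

__all__ = [
    "HyperbolicDisc",
    "angular_separation",
    "hyperbolic_distance",
    "connection_probability",
    "infer_beta",
    "infer_kappa",
    "infer_angles",
    "to_disc",
    "embed",
    "align_disc",
    "disc_distance_matrix",
    "disc_probability_matrix",
    "graph_loglik",
]

BETA_RANGE = (1.05, 25.0)
KAPPA_FLOOR = 1e-5


@dataclass
class HyperbolicDisc:
    """Per-node polar coordinates plus the hidden variables behind them."""

    r: np.ndarray
    theta: np.ndarray
    kappa: np.ndarray
    beta: float
    mu: float
    node_labels: list[str] = field(default_factory=list)
    loglik: float = float("nan")
    beta_warning: bool = False

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float) % (2.0 * np.pi)
        self.kappa = np.asarray(self.kappa, dtype=float)
        if not (self.r.shape == self.theta.shape == self.kappa.shape):
            raise ValueError("r, theta, kappa must have matching shapes")
        if not self.node_labels:
            self.node_labels = [str(i) for i in range(self.r.size)]

    @property
    def n_nodes(self) -> int:
        return self.r.size

    @property
    def r_hat(self) -> float:
        """Outermost radial coordinate among embedded nodes."""
        return float(np.max(self.r))


def angular_separation(theta_i, theta_j):
    """Shorter arc between two angles, in [0, pi]."""
    diff = np.abs(np.asarray(theta_i, dtype=float) - np.asarray(theta_j, dtype=float))
    diff = diff % (2.0 * np.pi)
    return np.pi - np.abs(np.pi - diff)


def hyperbolic_distance(r_i, r_j, dtheta, exact: bool = False):
    """Distance between disc points at radii (r_i, r_j), separation dtheta.

    Default kernel is the large-distance approximation
    ``r_i + r_j + 2 ln(dtheta / 2)`` floored at ``|r_i - r_j|``;
    ``exact=True`` uses the hyperbolic law of cosines.
    """
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    dtheta = np.asarray(dtheta, dtype=float)
    if exact:
        arg = np.cosh(r_i) * np.cosh(r_j) - np.sinh(r_i) * np.sinh(r_j) * np.cos(
            dtheta
        )
        return np.arccosh(np.maximum(arg, 1.0))
    with np.errstate(divide="ignore"):
        approx = r_i + r_j + 2.0 * np.log(dtheta / 2.0)
    return np.where(dtheta > 0.0, np.maximum(approx, np.abs(r_i - r_j)),
                    np.abs(r_i - r_j))


def connection_probability(d, beta: float, r_hat: float):
    """Sigmoid connection kernel, probability 1/2 exactly at d == r_hat."""
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    return expit(-0.5 * beta * (np.asarray(d, dtype=float) - r_hat))


# ---------------------------------------------------------------------------
# likelihood machinery in (kappa, theta) space


def _pair_loglik_terms(chi: np.ndarray, beta: float, adj: np.ndarray) -> np.ndarray:
    """a*ln p + (1-a)*ln(1-p) for p = 1/(1 + chi**beta), computed stably."""
    with np.errstate(divide="ignore"):
        s = beta * np.log(chi)
    # log(1 + chi^beta) without overflow; ln(1-p) ~ 0 deep in the tail
    big = s > 30.0
    log1p_s = np.where(big, s, np.log1p(np.exp(np.minimum(s, 30.0))))
    ln_q = np.where(big, 0.0, np.minimum(s, 30.0) - np.log1p(np.exp(np.minimum(s, 30.0))))
    return np.where(adj, -log1p_s, ln_q)


def graph_loglik(
    g: BinaryGraph, kappa: np.ndarray, theta: np.ndarray, beta: float, mu: float
) -> float:
    """Bernoulli log-likelihood of the graph under the circle model."""
    chi = _s1model.chi_matrix(kappa, theta, beta, mu)
    terms = _pair_loglik_terms(chi, beta, g.adj)
    iu = np.triu_indices(g.n_nodes, k=1)
    return float(terms[iu].sum())


def _mean_local_clustering(adj: np.ndarray) -> float:
    a = adj.astype(float)
    deg = a.sum(axis=1)
    tri = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    mask = deg >= 2
    if not mask.any():
        return 0.0
    coef = np.zeros_like(deg)
    coef[mask] = tri[mask] / (deg[mask] * (deg[mask] - 1) / 2.0)
    return float(coef[mask].mean())


def infer_beta(
    g: BinaryGraph,
    tol: float = 0.01,
    seed: int = 0,
    n_draws: int = 2,
    beta_range: tuple[float, float] = BETA_RANGE,
) -> tuple[float, bool]:
    """Bisection on beta matching synthetic to observed mean local clustering.

    Returns ``(beta_hat, warning)``; the warning flags a boundary hit (no beta
    in range reproduces the observed clustering).
    """
    if not g.is_connected():
        raise ValueError("graph must be connected; extract the LCC first")
    degrees = g.degrees
    if degrees.mean() < 2:
        raise ValueError("mean degree must be at least 2 for beta inference")
    c_obs = _mean_local_clustering(g.adj)
    rng = np.random.default_rng(seed)

    def synthetic_clustering(beta: float) -> float:
        mu = _s1model.mu_from_beta(beta, float(degrees.mean()))
        kappa = infer_kappa(g, beta, tol=1.0, max_iter=120)
        cs = []
        for _ in range(n_draws):
            theta = rng.uniform(0.0, 2.0 * np.pi, size=g.n_nodes)
            p = _s1model.connection_prob_matrix(kappa, theta, beta, mu)
            u = rng.random(p.shape)
            upper = np.triu(u < p, k=1)
            cs.append(_mean_local_clustering(upper | upper.T))
        return float(np.mean(cs))

    lo, hi = beta_range
    c_lo = synthetic_clustering(lo)
    if c_obs <= c_lo + tol:
        return lo, c_obs < c_lo - tol
    c_hi = synthetic_clustering(hi)
    if c_obs >= c_hi:
        return hi, True
    for _ in range(12):
        mid = 0.5 * (lo + hi)
        c_mid = synthetic_clustering(mid)
        if abs(c_mid - c_obs) < tol:
            return mid, False
        if c_mid < c_obs:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), False


def infer_kappa(
    g: BinaryGraph,
    beta: float,
    tol: float = 0.3,
    max_iter: int = 400,
    eta: float = 0.5,
) -> np.ndarray:
    """Fit hidden degrees so mean-field expected degrees match observed ones.

    Damped fixed-point iteration ``kappa += eta * (k - E[k])`` floored at a
    small positive value; returns the best iterate if the tolerance is not
    reached within ``max_iter``.
    """
    if beta <= 1:
        raise ValueError(f"beta must exceed 1, got {beta}")
    k = g.degrees.astype(float)
    mu = _s1model.mu_from_beta(beta, float(k.mean()))
    kappa = np.maximum(k.copy(), KAPPA_FLOOR)
    best = kappa.copy()
    best_err = np.inf
    for _ in range(max_iter):
        expected = _s1model.expected_degrees(kappa, beta, mu)
        err = np.max(np.abs(k - expected))
        if err < best_err:
            best_err = err
            best = kappa.copy()
        if err < tol:
            return kappa
        kappa = np.maximum(kappa + eta * (k - expected), KAPPA_FLOOR)
    return best


def infer_angles(
    g: BinaryGraph,
    kappa: np.ndarray,
    beta: float,
    mu: float | None = None,
    passes: int = 12,
    seed: int = 0,
    n_candidates: int = 72,
    loglik_tol: float = 1e-4,
    init_jitter: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Angular coordinates by spectral initialization + likelihood sweeps.

    Initial angles come from the two leading nontrivial eigenvectors of the
    degree-normalized adjacency; refinement visits nodes in a shuffled order,
    re-optimizing each angle over an equispaced candidate grid followed by
    golden-section polish of the node's conditional log-likelihood.  Sweeps
    stop when a full pass improves the total log-likelihood by less than
    ``loglik_tol`` (relative to its magnitude).
    """
    if not g.is_connected():
        raise ValueError("graph must be connected; extract the LCC first")
    if mu is None:
        mu = _s1model.mu_from_beta(beta, float(g.degrees.mean()))
    n = g.n_nodes
    rng = np.random.default_rng(seed)
    adj = g.adj
    radius = n / (2.0 * np.pi)

    theta = _spectral_angles(adj)
    if init_jitter > 0.0:
        theta = (theta + rng.normal(0.0, init_jitter, size=n)) % (2.0 * np.pi)

    grid = 2.0 * np.pi * np.arange(n_candidates) / n_candidates
    half_step = np.pi / n_candidates

    def node_loglik(i: int, phis: np.ndarray) -> np.ndarray:
        """Conditional log-likelihood of node i at each candidate angle."""
        others = np.delete(np.arange(n), i)
        dtheta = angular_separation(phis[:, None], theta[others][None, :])
        chi = radius * dtheta / (mu * kappa[i] * kappa[others][None, :])
        chi = np.maximum(chi, _s1model.CHI_EPS)
        terms = _pair_loglik_terms(chi, beta, adj[i, others][None, :])
        return terms.sum(axis=1)

    total = graph_loglik(g, kappa, theta, beta, mu)
    for _ in range(passes):
        order = rng.permutation(n)
        for i in order:
            cands = np.concatenate([grid, [theta[i]]])
            lls = node_loglik(i, cands)
            best = int(np.argmax(lls))
            lo = cands[best] - half_step
            hi = cands[best] + half_step
            phi, _ = _golden_section(lambda x, i=i: float(node_loglik(i, np.array([x]))[0]), lo, hi)
            cur_ll = lls[-1]
            new_ll = float(node_loglik(i, np.array([phi]))[0])
            if new_ll > cur_ll:
                theta[i] = phi % (2.0 * np.pi)
        new_total = graph_loglik(g, kappa, theta, beta, mu)
        if new_total - total < loglik_tol * max(1.0, abs(new_total)):
            total = max(new_total, total)
            break
        total = new_total
    return theta, total


def _spectral_angles(adj: np.ndarray) -> np.ndarray:
    deg = adj.sum(axis=1).astype(float)
    inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1.0))
    a_norm = adj * np.outer(inv_sqrt, inv_sqrt)
    vals, vecs = np.linalg.eigh(a_norm)
    # last eigenvector is the trivial Perron mode; next two give the circle
    v1 = vecs[:, -2] * inv_sqrt
    v2 = vecs[:, -3] * inv_sqrt
    return np.arctan2(v2, v1) % (2.0 * np.pi)


_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _golden_section(f, lo: float, hi: float, iters: int = 18) -> tuple[float, float]:
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    return (c, fc) if fc > fd else (d, fd)


def to_disc(
    kappa: np.ndarray,
    theta: np.ndarray,
    beta: float,
    mu: float | None = None,
    node_labels: list[str] | None = None,
    loglik: float = float("nan"),
    beta_warning: bool = False,
) -> HyperbolicDisc:
    """Map hidden degrees to radial coordinates on the hyperbolic disc.

    ``r_i = R_disc - 2 ln(kappa_i / kappa_min)`` with
    ``R_disc = 2 ln(n / (mu * pi * kappa_min**2))``: larger hidden degree,
    closer to the center; the smallest hidden degree sits at ``R_disc``.
    """
    kappa = np.asarray(kappa, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(kappa <= 0):
        raise ValueError("all hidden degrees must be positive")
    if mu is None:
        mu = _s1model.mu_from_beta(beta, float(kappa.mean()))
    n = kappa.size
    kappa_min = float(kappa.min())
    r_disc = 2.0 * np.log(n / (mu * np.pi * kappa_min**2))
    r = r_disc - 2.0 * np.log(kappa / kappa_min)
    return HyperbolicDisc(
        r=r,
        theta=theta,
        kappa=kappa,
        beta=beta,
        mu=mu,
        node_labels=node_labels or [],
        loglik=loglik,
        beta_warning=beta_warning,
    )


def embed(
    g: BinaryGraph,
    seed: int = 0,
    beta: float | None = None,
    passes: int = 12,
) -> HyperbolicDisc:
    """Full inference: beta -> hidden degrees -> angles -> disc coordinates."""
    if g.n_nodes < 10:
        raise ValueError("need at least 10 nodes to embed")
    if not g.is_connected():
        raise ValueError("graph must be connected; extract the LCC first")
    warning = False
    if beta is None:
        beta, warning = infer_beta(g, seed=seed)
    kappa = infer_kappa(g, beta)
    mu = _s1model.mu_from_beta(beta, float(g.degrees.mean()))
    theta, loglik = infer_angles(g, kappa, beta, mu=mu, passes=passes, seed=seed)
    return to_disc(
        kappa,
        theta,
        beta,
        mu=mu,
        node_labels=list(g.node_labels),
        loglik=loglik,
        beta_warning=warning,
    )


def align_disc(
    disc: HyperbolicDisc, reference_nodes, reflect: bool = False
) -> HyperbolicDisc:
    """Rotate so the circular mean angle of the reference set is zero.

    Optional reflection (theta -> -theta) is applied first.  Radial
    coordinates, and hence all pairwise distances, are unchanged.
    """
    ref = np.asarray(list(reference_nodes), dtype=int)
    if ref.size == 0:
        raise ValueError("reference node set must be non-empty")
    theta = disc.theta.copy()
    if reflect:
        theta = (-theta) % (2.0 * np.pi)
    z = np.exp(1j * theta[ref]).mean()
    if np.abs(z) < 1e-9:
        raise ValueError("circular mean of reference set is undefined (resultant ~ 0)")
    rotation = np.angle(z)
    return HyperbolicDisc(
        r=disc.r.copy(),
        theta=(theta - rotation) % (2.0 * np.pi),
        kappa=disc.kappa.copy(),
        beta=disc.beta,
        mu=disc.mu,
        node_labels=list(disc.node_labels),
        loglik=disc.loglik,
        beta_warning=disc.beta_warning,
    )


def disc_distance_matrix(disc: HyperbolicDisc, exact: bool = False) -> np.ndarray:
    """Pairwise hyperbolic distances between embedded nodes."""
    dtheta = _s1model.angular_separation_matrix(disc.theta)
    d = hyperbolic_distance(disc.r[:, None], disc.r[None, :], dtheta, exact=exact)
    np.fill_diagonal(d, 0.0)
    return d


def disc_probability_matrix(disc: HyperbolicDisc, exact: bool = False) -> np.ndarray:
    """Pairwise connection probabilities implied by the embedded disc."""
    d = disc_distance_matrix(disc, exact=exact)
    p = connection_probability(d, disc.beta, disc.r_hat)
    np.fill_diagonal(p, 0.0)
    return p
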