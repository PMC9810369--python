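"""Shared kernels of the S1 geometric network model.

Nodes live on a circle of radius ``R = n / (2 pi)`` and carry hidden degrees
``kappa``.  An unordered pair ``(i, j)`` is connected with probability

    p_ij = 1 / (1 + chi_ij ** beta),   chi_ij = R * dtheta_ij / (mu * k_i * k_j)

where ``beta > 1`` controls clustering and ``mu`` sets the mean degree.  Both
the synthetic generator and the maximum-likelihood inference use these
functions, so they live in one place.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "mu_from_beta",
    "sample_powerlaw_kappa",
    "angular_separation_matrix",
    "chi_matrix",
    "connection_prob_matrix",
    "mean_connection_prob",
    "expected_degrees",
]

#: floor applied to chi to keep log-likelihoods finite at dtheta == 0
CHI_EPS = 1e-12


def mu_from_beta(beta: float, mean_degree: float) -> float:
    """Mean-field normalization tying ``mu`` to a target mean degree.

    With ``mu = beta * sin(pi / beta) / (2 * pi * <k>)`` and hidden degrees
    scaled so that ``<kappa> = <k>``, the expected degree of node ``i`` is
    ``kappa_i`` in the large-n limit.
    """
    if beta <= 1:
        raise ValueError(f"beta must exceed 1 (got {beta})")
    if mean_degree <= 0:
        raise ValueError(f"mean_degree must be positive (got {mean_degree})")
    return beta * np.sin(np.pi / beta) / (2.0 * np.pi * mean_degree)


def sample_powerlaw_kappa(
    n_nodes: int,
    gamma: float,
    mean_degree: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Power-law hidden degrees with finite-size truncation.

    Pareto(exponent ``gamma``) samples truncated at ``kappa_max =
    n ** (1 / (gamma - 1))`` (natural cutoff, avoids condensation on a
    single hub), then rescaled to mean ``mean_degree``.
    """
    if gamma <= 1:
        raise ValueError(f"gamma must exceed 1 (got {gamma})")
    kappa_max = float(n_nodes) ** (1.0 / (gamma - 1.0))
    # inverse-CDF sampling of a truncated Pareto with x_min = 1
    u = rng.random(n_nodes)
    a = gamma - 1.0
    cdf_max = 1.0 - kappa_max ** (-a)
    kappa = (1.0 - u * cdf_max) ** (-1.0 / a)
    kappa *= mean_degree / kappa.mean()
    return kappa


def angular_separation_matrix(theta: np.ndarray) -> np.ndarray:
    """Pairwise angular separations in [0, pi]."""
    diff = np.abs(theta[:, None] - theta[None, :]) % (2.0 * np.pi)
    return np.pi - np.abs(np.pi - diff)


def chi_matrix(
    kappa: np.ndarray, theta: np.ndarray, beta: float, mu: float
) -> np.ndarray:
    n = kappa.size
    radius = n / (2.0 * np.pi)
    dtheta = angular_separation_matrix(theta)
    chi = radius * dtheta / (mu * np.outer(kappa, kappa))
    np.fill_diagonal(chi, np.inf)
    return np.maximum(chi, CHI_EPS)


def connection_prob_matrix(
    kappa: np.ndarray, theta: np.ndarray, beta: float, mu: float
) -> np.ndarray:
    """Pairwise connection probabilities; diagonal forced to 0."""
    chi = chi_matrix(kappa, theta, beta, mu)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + chi**beta)
    np.fill_diagonal(p, 0.0)
    return p


# -- mean-field machinery ----------------------------------------------------
#
# Averaging the connection probability over a uniform angular separation
# requires F(L) = integral_0^L du / (1 + u**beta), which has no elementary
# closed form; a per-beta log-grid cumulative quadrature is cached instead.

_F_CACHE: dict[float, tuple[np.ndarray, np.ndarray, float]] = {}


def _f_table(beta: float) -> tuple[np.ndarray, np.ndarray, float]:
    key = round(float(beta), 12)
    if key not in _F_CACHE:
        t = np.linspace(np.log(1e-9), np.log(1e9), 6000)
        u = np.exp(t)
        integrand = u / (1.0 + u**beta)  # du = u dt
        cum = np.concatenate(
            [[0.0], np.cumsum((integrand[1:] + integrand[:-1]) / 2.0 * np.diff(t))]
        )
        cum += u[0]  # integrand ~ 1 below u_min
        full = np.pi / (beta * np.sin(np.pi / beta))
        _F_CACHE[key] = (t, cum, full)
    return _F_CACHE[key]


def mean_connection_prob(a: np.ndarray, beta: float) -> np.ndarray:
    """E over uniform dtheta in [0, pi] of 1 / (1 + (dtheta / a)**beta).

    ``a = mu * kappa_i * kappa_j / R`` is the angular scale of the pair.
    """
    t, cum, full = _f_table(beta)
    a = np.asarray(a, dtype=float)
    L = np.pi / np.maximum(a, 1e-300)
    F = np.where(L >= np.exp(t[-1]), full, np.interp(np.log(L), t, cum))
    return np.minimum(a / np.pi * F, 1.0)


def expected_degrees(kappa: np.ndarray, beta: float, mu: float) -> np.ndarray:
    """Mean-field expected degree of every node at uniform angles."""
    n = kappa.size
    radius = n / (2.0 * np.pi)
    a = mu * np.outer(kappa, kappa) / radius
    pbar = mean_connection_prob(a, beta)
    np.fill_diagonal(pbar, 0.0)
    return pbar.sum(axis=1)
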