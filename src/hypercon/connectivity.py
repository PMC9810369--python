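"""Correlation matrices, absolute-value thresholding, and threshold selection.

The selection procedure scans a grid of thresholds; a threshold is admissible
for a subject when (a) the binary graph keeps at least a given fraction of
nodes in its largest connected component and (b) the degree distribution
passes a scale-free check.  The per-subject admissible window feeds a group
threshold chosen to satisfy the most subjects, ties resolved toward the
sparser network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._powerlaw import bootstrap_gof, fit_discrete_powerlaw
from .types import BinaryGraph, CorrelationMatrix, SeriesMatrix

__all__ = [
    "CorrelationMatrix",
    "BinaryGraph",
    "DegreeCheck",
    "ThresholdWindow",
    "sample_variance",
    "pearson_matrix",
    "threshold_graph",
    "largest_component",
    "min_nodes_for_retention",
    "scale_free_check",
    "threshold_window",
    "group_threshold",
]

DEFAULT_GRID = (0.15, 0.65, 0.01)
DEFAULT_RETENTION = 0.95
GOF_PASS_P = 0.1


@dataclass(frozen=True)
class DegreeCheck:
    degrees: np.ndarray
    alpha_hat: float
    k_min_hat: int
    gof_p: float
    passes: bool


@dataclass
class ThresholdWindow:
    grid: np.ndarray
    retention: np.ndarray
    scale_free: np.ndarray
    alpha_hat: np.ndarray
    gof_p: np.ndarray
    window: tuple[float, float] | None = None
    retention_fraction: float = DEFAULT_RETENTION

    def admissible(self) -> np.ndarray:
        return (self.retention >= self.retention_fraction) & self.scale_free


def sample_variance(x) -> float:
    """Unbiased sample variance, sum((x - mean)^2) / (n - 1)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("sample variance undefined for fewer than 2 observations")
    return float(np.sum((x - x.mean()) ** 2) / (x.size - 1))


def pearson_matrix(ts: SeriesMatrix) -> CorrelationMatrix:
    """Sample Pearson correlation between every pair of rows."""
    values = ts.values
    stds = values.std(axis=1, ddof=1)
    bad = np.flatnonzero(stds == 0.0)
    if bad.size:
        names = ", ".join(ts.node_labels[i] for i in bad)
        raise ValueError(f"constant series (zero variance) for node(s): {names}")
    rho = np.corrcoef(values)
    rho = np.clip(rho, -1.0, 1.0)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(rho=rho, node_labels=list(ts.node_labels))


def threshold_graph(
    c: CorrelationMatrix, tau: float, use_abs: bool = True
) -> BinaryGraph:
    """Binary graph with an edge wherever |rho| (or rho) strictly exceeds tau."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    vals = np.abs(c.rho) if use_abs else c.rho
    adj = vals > tau
    np.fill_diagonal(adj, False)
    return BinaryGraph(adj=adj, node_labels=list(c.node_labels), threshold=tau)


def largest_component(g: BinaryGraph) -> tuple[BinaryGraph, float]:
    """Induced subgraph on the largest connected component and its retention."""
    if g.n_nodes == 0:
        raise ValueError("graph is empty")
    mask = g.lcc_mask
    idx = np.flatnonzero(mask)
    sub = BinaryGraph(
        adj=g.adj[np.ix_(idx, idx)],
        node_labels=[g.node_labels[i] for i in idx],
        threshold=g.threshold,
    )
    return sub, float(idx.size) / g.n_nodes


def min_nodes_for_retention(n_nodes: int, fraction: float) -> int:
    """Smallest node count meeting a retention fraction (ceiling rule)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    return int(np.ceil(fraction * n_nodes - 1e-12))


def scale_free_check(
    degrees,
    gof_reps: int = 50,
    seed: int = 0,
    p_threshold: float = GOF_PASS_P,
) -> DegreeCheck:
    """Maximum-likelihood power-law fit plus bootstrap goodness of fit.

    ``passes`` requires the bootstrap p-value to reach ``p_threshold`` and the
    fitted tail to be non-degenerate: at least four distinct degree values and
    an exponent away from the search boundary.  Degenerate inputs (regular
    graphs, near-constant degrees) fail rather than fit.
    """
    degrees = np.asarray(degrees, dtype=int)
    positive = degrees[degrees > 0]
    if positive.size < 20:
        raise ValueError(
            f"need at least 20 nonzero degrees for a power-law fit, got {positive.size}"
        )
    n_distinct = np.unique(positive).size
    if n_distinct < 4:
        return DegreeCheck(
            degrees=degrees, alpha_hat=float("nan"), k_min_hat=int(positive.min()),
            gof_p=0.0, passes=False,
        )
    fit = fit_discrete_powerlaw(positive)
    rng = np.random.default_rng(seed)
    gof_p = bootstrap_gof(positive, fit, n_reps=gof_reps, rng=rng)
    tail = positive[positive >= fit.k_min]
    passes = (
        gof_p >= p_threshold
        and np.unique(tail).size >= 4
        and fit.alpha < 5.8
    )
    return DegreeCheck(
        degrees=degrees,
        alpha_hat=fit.alpha,
        k_min_hat=fit.k_min,
        gof_p=gof_p,
        passes=bool(passes),
    )


def threshold_window(
    c: CorrelationMatrix,
    grid_lo: float = DEFAULT_GRID[0],
    grid_hi: float = DEFAULT_GRID[1],
    step: float = DEFAULT_GRID[2],
    retention_fraction: float = DEFAULT_RETENTION,
    gof_reps: int = 50,
    seed: int = 0,
    use_abs: bool = True,
) -> ThresholdWindow:
    """Scan thresholds; record retention and scale-free pass at each.

    The window is the longest contiguous run of admissible thresholds
    (retention and scale-freeness both satisfied); among equally long runs the
    one at higher thresholds wins (sparser networks preferred).
    """
    if grid_lo >= grid_hi:
        raise ValueError("grid_lo must be below grid_hi")
    if step <= 0:
        raise ValueError("step must be positive")
    n_steps = int(round((grid_hi - grid_lo) / step))
    grid = grid_lo + step * np.arange(n_steps + 1)
    grid = grid[grid <= grid_hi + 1e-9]

    retention = np.zeros(grid.size)
    passes = np.zeros(grid.size, dtype=bool)
    alpha = np.full(grid.size, np.nan)
    gof_p = np.full(grid.size, np.nan)
    for k, tau in enumerate(grid):
        g = threshold_graph(c, float(tau), use_abs=use_abs)
        _, retention[k] = largest_component(g)
        try:
            check = scale_free_check(g.degrees, gof_reps=gof_reps, seed=seed)
        except ValueError:
            continue
        passes[k] = check.passes
        alpha[k] = check.alpha_hat
        gof_p[k] = check.gof_p

    admissible = (retention >= retention_fraction) & passes
    window = _longest_run(grid, admissible)
    return ThresholdWindow(
        grid=grid,
        retention=retention,
        scale_free=passes,
        alpha_hat=alpha,
        gof_p=gof_p,
        window=window,
        retention_fraction=retention_fraction,
    )


def _longest_run(
    grid: np.ndarray, admissible: np.ndarray
) -> tuple[float, float] | None:
    best: tuple[int, int] | None = None
    start = None
    for k, ok in enumerate(admissible):
        if ok and start is None:
            start = k
        if (not ok or k == admissible.size - 1) and start is not None:
            end = k if ok else k - 1
            if best is None or (end - start) >= (best[1] - best[0]):
                best = (start, end)
            start = None
    if best is None:
        return None
    return float(grid[best[0]]), float(grid[best[1]])


def group_threshold(windows: list[ThresholdWindow]) -> float:
    """Grid value inside the most subject windows; ties go to the larger value."""
    if not windows:
        raise ValueError("need at least one window")
    non_empty = [w for w in windows if w.window is not None]
    if not non_empty:
        raise ValueError("no subject has a valid threshold window")
    grid = non_empty[0].grid
    counts = np.zeros(grid.size, dtype=int)
    for w in non_empty:
        lo, hi = w.window
        counts += (grid >= lo - 1e-9) & (grid <= hi + 1e-9)
    best = counts.max()
    # ties broken by the larger threshold (sparser network)
    return float(grid[np.flatnonzero(counts == best)[-1]])
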