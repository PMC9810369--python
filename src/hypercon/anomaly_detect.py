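"""Embedding reproducibility and individual-vs-cohort edge anomaly detection.

Reproducibility: embed one graph many times, transform each distance matrix
to the distance analog ``exp((d - R_hat) / 2)``, and compute per-edge
coefficients of variation.  Detection: build per-edge empirical distributions
of a control cohort's values (hyperbolic distances or correlations) and flag
a test subject's edges falling in the tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .s1h2 import HyperbolicDisc, disc_distance_matrix, embed
from .types import BinaryGraph, CorrelationMatrix

__all__ = [
    "CVReport",
    "ControlDistribution",
    "AnomalyReport",
    "distance_analog",
    "repeat_embed_cv",
    "build_control",
    "flag_edges",
    "flag_edges_correlation",
    "aggregate_regions",
]

DEFAULT_TAIL = 0.025
DEFAULT_REPS = 100


@dataclass
class CVReport:
    edges: np.ndarray  # (m, 2) node pairs, i < j
    edge_cv: np.ndarray
    node_cv: np.ndarray  # NaN for nodes without incident edges
    n_repetitions: int
    n_failed: int = 0


@dataclass
class ControlDistribution:
    """Per node pair: control samples plus summary statistics and cut points."""

    samples: np.ndarray  # (n_subjects, n, n)
    mean: np.ndarray
    sd: np.ndarray
    lo_cut: np.ndarray
    hi_cut: np.ndarray
    normality_p: np.ndarray
    tail: float
    cut_method: str = "parametric"
    node_labels: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return self.samples.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.samples.shape[1]


@dataclass
class AnomalyReport:
    long_edges: list[tuple[int, int]]
    short_edges: list[tuple[int, int]]
    percentile: np.ndarray  # (n, n) empirical CDF position of the test value
    mode: str
    tail: float
    node_labels: list[str] = field(default_factory=list)


def distance_analog(d: np.ndarray, r_hat: float) -> np.ndarray:
    """Elementwise exp((d - r_hat) / 2); equals 1 exactly at d == r_hat."""
    if not np.isfinite(r_hat):
        raise ValueError("r_hat must be finite")
    return np.exp((np.asarray(d, dtype=float) - r_hat) / 2.0)


def repeat_embed_cv(
    g: BinaryGraph,
    n_rep: int = DEFAULT_REPS,
    base_seed: int = 0,
    beta: float | None = None,
) -> CVReport:
    """Coefficient of variation of the distance analog over repeated embeddings.

    Seeds run ``base_seed .. base_seed + n_rep - 1``.  A failed repetition is
    recorded and excluded; at least 80% must succeed.  ``beta`` may be pinned
    to skip per-repetition clustering calibration.
    """
    if n_rep < 2:
        raise ValueError("need at least 2 repetitions")
    edges = g.edge_list()
    analogs = []
    n_failed = 0
    for k in range(n_rep):
        try:
            disc = embed(g, seed=base_seed + k, beta=beta)
        except (ValueError, FloatingPointError):
            n_failed += 1
            continue
        d = disc_distance_matrix(disc)
        analogs.append(distance_analog(d, disc.r_hat)[edges[:, 0], edges[:, 1]])
    if len(analogs) < max(2, int(np.ceil(0.8 * n_rep))):
        raise RuntimeError(
            f"only {len(analogs)}/{n_rep} embeddings succeeded (need 80%)"
        )
    stack = np.vstack(analogs)
    edge_cv = stack.std(axis=0, ddof=1) / stack.mean(axis=0)
    node_cv = np.full(g.n_nodes, np.nan)
    for v in range(g.n_nodes):
        incident = (edges[:, 0] == v) | (edges[:, 1] == v)
        if incident.any():
            node_cv[v] = edge_cv[incident].mean()
    return CVReport(
        edges=edges,
        edge_cv=edge_cv,
        node_cv=node_cv,
        n_repetitions=len(analogs),
        n_failed=n_failed,
    )


def build_control(
    cohort_values: list[np.ndarray],
    tail: float = DEFAULT_TAIL,
    node_labels: list[str] | None = None,
    min_subjects: int = 20,
    normality: bool = True,
    cut_method: str = "parametric",
    quantile_method: str = "median_unbiased",
) -> ControlDistribution:
    """Per-edge control distribution from a cohort of symmetric value matrices.

    The default ``parametric`` cuts are Student-t prediction bounds,
    ``mean -/+ t_{n-1}(1 - tail) * sqrt(1 + 1/n) * sd``: under per-edge
    normality (which the retained Shapiro-Wilk p-values monitor) a fresh
    control-law draw lands beyond each cut with probability exactly ``tail``.
    ``cut_method="empirical"`` switches to distribution-free quantiles
    (median-unbiased plotting position); note that no empirical rule can be
    exactly calibrated — attainable null rates are multiples of
    ``1 / (n_subjects + 1)``.
    """
    if len(cohort_values) < min_subjects:
        raise ValueError(
            f"need at least {min_subjects} control subjects, got {len(cohort_values)}"
        )
    if not 0.0 < tail < 0.5:
        raise ValueError(f"tail must lie in (0, 0.5), got {tail}")
    shapes = {m.shape for m in cohort_values}
    if len(shapes) > 1:
        bad = [k for k, m in enumerate(cohort_values) if m.shape != cohort_values[0].shape]
        raise ValueError(f"node-set mismatch across control subjects: {bad}")
    if cut_method not in ("parametric", "empirical"):
        raise ValueError(f"unknown cut_method {cut_method!r}")
    samples = np.stack([np.asarray(m, dtype=float) for m in cohort_values])
    mean = samples.mean(axis=0)
    sd = samples.std(axis=0, ddof=1)
    lo_cut, hi_cut = _cuts(samples, mean, sd, tail, cut_method, quantile_method)
    n = samples.shape[1]
    normality_p = np.full((n, n), np.nan)
    if normality:
        iu = np.triu_indices(n, k=1)
        for i, j in zip(*iu):
            vals = samples[:, i, j]
            if np.ptp(vals) > 0:
                normality_p[i, j] = normality_p[j, i] = stats.shapiro(vals).pvalue
    return ControlDistribution(
        samples=samples,
        mean=mean,
        sd=sd,
        lo_cut=lo_cut,
        hi_cut=hi_cut,
        normality_p=normality_p,
        tail=tail,
        cut_method=cut_method,
        node_labels=node_labels or [str(i) for i in range(n)],
    )


def _cuts(
    samples: np.ndarray,
    mean: np.ndarray,
    sd: np.ndarray,
    tail: float,
    cut_method: str,
    quantile_method: str = "median_unbiased",
) -> tuple[np.ndarray, np.ndarray]:
    if cut_method == "parametric":
        n_subj = samples.shape[0]
        width = stats.t.ppf(1.0 - tail, n_subj - 1) * np.sqrt(1.0 + 1.0 / n_subj)
        return mean - width * sd, mean + width * sd
    lo = np.quantile(samples, tail, axis=0, method=quantile_method)
    hi = np.quantile(samples, 1.0 - tail, axis=0, method=quantile_method)
    return lo, hi


def _flag(
    test: np.ndarray, control: ControlDistribution, tail: float, mode: str
) -> AnomalyReport:
    n = control.n_nodes
    if test.shape != (n, n):
        raise ValueError("test matrix does not match the control node set")
    if not 0.0 < tail < 0.5:
        raise ValueError(f"tail must lie in (0, 0.5), got {tail}")
    if abs(tail - control.tail) > 1e-12:
        lo_cut, hi_cut = _cuts(control.samples, control.mean, control.sd, tail,
                               control.cut_method)
    else:
        lo_cut, hi_cut = control.lo_cut, control.hi_cut
    percentile = (control.samples < test[None, :, :]).mean(axis=0)
    long_edges, short_edges = [], []
    iu = np.triu_indices(n, k=1)
    for i, j in zip(*iu):
        v = test[i, j]
        if v > hi_cut[i, j]:
            long_edges.append((int(i), int(j)))
        elif v < lo_cut[i, j]:
            short_edges.append((int(i), int(j)))
    return AnomalyReport(
        long_edges=long_edges,
        short_edges=short_edges,
        percentile=percentile,
        mode=mode,
        tail=tail,
        node_labels=list(control.node_labels),
    )


def flag_edges(
    test: np.ndarray, control: ControlDistribution, tail: float = DEFAULT_TAIL
) -> AnomalyReport:
    """Flag pairs whose test distance falls strictly outside the control cuts."""
    return _flag(np.asarray(test, dtype=float), control, tail, mode="hyperbolic")


def flag_edges_correlation(
    test: CorrelationMatrix,
    control_cohort: list[CorrelationMatrix],
    tail: float = DEFAULT_TAIL,
    min_subjects: int = 20,
) -> AnomalyReport:
    """Same machinery on per-edge correlation values instead of distances."""
    control = build_control(
        [c.rho for c in control_cohort],
        tail=tail,
        node_labels=list(test.node_labels),
        min_subjects=min_subjects,
        normality=False,
    )
    return _flag(np.asarray(test.rho, dtype=float), control, tail, mode="correlation")


def aggregate_regions(
    report: AnomalyReport, grouping: dict[int, str]
) -> dict[tuple[str, str], tuple[int, int]]:
    """Counts of (long, short) flags per unordered region pair."""
    flagged_nodes = {v for e in report.long_edges + report.short_edges for v in e}
    missing = sorted(v for v in flagged_nodes if v not in grouping)
    if missing:
        raise KeyError(f"grouping does not cover flagged node(s): {missing}")
    counts: dict[tuple[str, str], list[int]] = {}
    for edges, slot in ((report.long_edges, 0), (report.short_edges, 1)):
        for i, j in edges:
            key = tuple(sorted((grouping[i], grouping[j])))
            counts.setdefault(key, [0, 0])[slot] += 1
    return {k: (v[0], v[1]) for k, v in counts.items()}
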