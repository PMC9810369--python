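"""Shared fixtures: small canonical graphs and cached synthetic draws."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from hypercon import synthcohort as sc
from hypercon.connectivity import largest_component
from hypercon.types import BinaryGraph


def graph_from_networkx(g) -> BinaryGraph:
    return BinaryGraph(adj=nx.to_numpy_array(g).astype(bool))


def graph_from_edges(n: int, edges) -> BinaryGraph:
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    return BinaryGraph(adj=adj)


def circular_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher-Lee pairwise circular correlation (rotation-invariant; take
    the absolute value to also absorb reflection).

    The pairwise form stays informative when angles concentrate on arcs,
    where mean-direction-centered statistics degenerate.
    """
    da = a[:, None] - a[None, :]
    db = b[:, None] - b[None, :]
    iu = np.triu_indices(a.size, 1)
    sa, sb = np.sin(da[iu]), np.sin(db[iu])
    return float(np.sum(sa * sb) / np.sqrt(np.sum(sa**2) * np.sum(sb**2)))


@pytest.fixture(scope="session")
def s1_draw_300():
    """One 300-node circle-model draw (LCC) with its aligned ground truth."""
    gt = sc.make_powerlaw_ground_truth(300, gamma=2.7, mean_degree=10.0,
                                       beta=2.5, seed=11)
    g = sc.gen_s1_network(gt, seed=12)
    mask = g.lcc_mask
    idx = np.flatnonzero(mask)
    lcc, _ = largest_component(g)
    gt_lcc = sc.GroundTruthS1(
        kappa=gt.kappa[idx], theta=gt.theta[idx], beta=gt.beta, mu=gt.mu
    )
    return lcc, gt_lcc


@pytest.fixture(scope="session")
def embedded_300(s1_draw_300):
    """The 300-node draw embedded once; reused by several expensive tests."""
    from hypercon import s1h2

    lcc, gt = s1_draw_300
    disc = s1h2.embed(lcc, seed=5)
    return lcc, gt, disc
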