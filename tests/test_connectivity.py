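import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypercon import connectivity as cn
from hypercon._powerlaw import sample_zipf
from hypercon.types import CorrelationMatrix, SeriesMatrix

from conftest import graph_from_edges


class TestSampleVariance:
    def test_textbook(self):
        assert cn.sample_variance([1, 2, 3]) == pytest.approx(1.0)

    def test_constant(self):
        assert cn.sample_variance([5, 5, 5, 5]) == 0.0

    def test_two_points(self):
        # hand evaluation: (0-1)^2 + (2-1)^2 over n-1 = 2
        assert cn.sample_variance([0, 2]) == pytest.approx(2.0)

    def test_too_short(self):
        with pytest.raises(ValueError, match="undefined"):
            cn.sample_variance([1.0])


class TestPearsonMatrix:
    def test_perfect_linear(self):
        ts = SeriesMatrix(values=[[1, 2, 3], [2, 4, 6]])
        assert cn.pearson_matrix(ts).rho[0, 1] == pytest.approx(1.0)

    def test_anticorrelation(self):
        ts = SeriesMatrix(values=[[1, 2, 3], [3, 2, 1]])
        assert cn.pearson_matrix(ts).rho[0, 1] == pytest.approx(-1.0)

    def test_hand_value(self):
        ts = SeriesMatrix(values=[[1, 2, 3, 4], [1, 3, 2, 4]])
        assert cn.pearson_matrix(ts).rho[0, 1] == pytest.approx(0.8)

    def test_constant_row_names_node(self):
        ts = SeriesMatrix(values=[[1, 2, 3], [7, 7, 7]], node_labels=["a", "b"])
        with pytest.raises(ValueError, match="b"):
            cn.pearson_matrix(ts)

    def test_unit_diagonal_and_symmetry(self):
        rng = np.random.default_rng(0)
        ts = SeriesMatrix(values=rng.standard_normal((6, 50)))
        c = cn.pearson_matrix(ts)
        assert np.allclose(np.diag(c.rho), 1.0)
        assert np.allclose(c.rho, c.rho.T)

    @given(slope=st.floats(0.1, 50), offset=st.floats(-10, 10))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, slope, offset):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((3, 40))
        scaled = base.copy()
        scaled[0] = slope * base[0] + offset
        r1 = cn.pearson_matrix(SeriesMatrix(values=base)).rho
        r2 = cn.pearson_matrix(SeriesMatrix(values=scaled)).rho
        assert np.allclose(r1, r2, atol=1e-9)

    def test_negative_slope_flips_sign(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal((2, 40))
        flipped = base.copy()
        flipped[0] = -base[0]
        r1 = cn.pearson_matrix(SeriesMatrix(values=base)).rho[0, 1]
        r2 = cn.pearson_matrix(SeriesMatrix(values=flipped)).rho[0, 1]
        assert r2 == pytest.approx(-r1)


def _corr(rho):
    return CorrelationMatrix(rho=np.array(rho, dtype=float))


class TestThresholdGraph:
    def test_maximal_threshold_empty(self):
        rng = np.random.default_rng(1)
        n = 5
        r = np.clip(rng.uniform(-0.9, 0.9, (n, n)), -0.99, 0.99)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        g = cn.threshold_graph(_corr(r), 1.0)
        assert g.n_edges == 0

    def test_zero_threshold_complete(self):
        r = np.full((4, 4), 0.3)
        np.fill_diagonal(r, 1.0)
        g = cn.threshold_graph(_corr(r), 0.0)
        assert g.n_edges == 6

    def test_toy_matrix_enumeration(self):
        r = np.array([[1.0, 0.5, -0.45], [0.5, 1.0, 0.2], [-0.45, 0.2, 1.0]])
        g = cn.threshold_graph(_corr(r), 0.4, use_abs=True)
        assert sorted(map(tuple, g.edge_list())) == [(0, 1), (0, 2)]

    def test_strict_inequality(self):
        r = np.array([[1.0, 0.4], [0.4, 1.0]])
        assert cn.threshold_graph(_corr(r), 0.4).n_edges == 0

    def test_abs_mode_sign_flip_invariance(self):
        rng = np.random.default_rng(2)
        r = np.clip(rng.uniform(-0.9, 0.9, (6, 6)), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        flipped = -r
        np.fill_diagonal(flipped, 1.0)
        g1 = cn.threshold_graph(_corr(r), 0.3, use_abs=True)
        g2 = cn.threshold_graph(_corr(flipped), 0.3, use_abs=True)
        assert np.array_equal(g1.adj, g2.adj)

    @given(t1=st.floats(0.0, 1.0), t2=st.floats(0.0, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_edge_monotonicity(self, t1, t2):
        t1, t2 = sorted((t1, t2))
        rng = np.random.default_rng(9)
        r = np.clip(rng.uniform(-1, 1, (8, 8)), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        lo = cn.threshold_graph(_corr(r), t1)
        hi = cn.threshold_graph(_corr(r), t2)
        assert np.all(lo.adj | ~hi.adj)  # edges at t2 subset of edges at t1


class TestLargestComponent:
    def test_connected(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        _, retention = cn.largest_component(g)
        assert retention == 1.0

    def test_two_components(self):
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (5, 6), (6, 7)]
        sub, retention = cn.largest_component(graph_from_edges(8, edges))
        assert retention == pytest.approx(0.625)
        assert sub.n_nodes == 5

    def test_edgeless_tie_break(self):
        sub, retention = cn.largest_component(graph_from_edges(4, []))
        assert retention == 0.25
        assert sub.node_labels == ["0"]  # smallest node id wins ties

    @given(st.integers(0, 2**15 - 1))
    @settings(max_examples=40, deadline=None)
    def test_oracle_small_graphs(self, bits):
        # exhaustive comparison against networkx components for n <= 6
        n = 6
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        edges = [p for k, p in enumerate(pairs) if bits >> k & 1]
        g = graph_from_edges(n, edges)
        sub, retention = cn.largest_component(g)
        comps = list(nx.connected_components(g.to_networkx()))
        expected = max(len(c) for c in comps)
        assert sub.n_nodes == expected
        assert retention == pytest.approx(expected / n)


class TestMinNodesForRetention:
    def test_274_nodes(self):
        assert cn.min_nodes_for_retention(274, 0.95) == 261

    def test_full_retention(self):
        assert cn.min_nodes_for_retention(100, 1.0) == 100

    def test_ceiling(self):
        assert cn.min_nodes_for_retention(10, 0.95) == 10

    @given(n=st.integers(1, 10_000), frac=st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_is_ceiling(self, n, frac):
        m = cn.min_nodes_for_retention(n, frac)
        assert m - 1 < frac * n <= m + 1e-9 * n


class TestScaleFreeCheck:
    def test_powerlaw_degrees_pass(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            degrees = sample_zipf(2.5, 1, 500, rng)
            hits += cn.scale_free_check(degrees, gof_reps=50, seed=seed).passes
        assert hits >= 18

    def test_regular_graph_fails(self):
        check = cn.scale_free_check(np.full(100, 6), gof_reps=20, seed=0)
        assert not check.passes

    def test_binomial_degrees_fail(self):
        fails = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            degrees = rng.binomial(200, 0.05, 500)
            fails += not cn.scale_free_check(degrees, gof_reps=50, seed=seed).passes
        assert fails >= 18

    def test_too_few_nodes(self):
        with pytest.raises(ValueError, match="at least 20"):
            cn.scale_free_check([3] * 10)


def _planted_band_matrix(seed=0):
    """Correlation stand-in where thresholds in (0.2, 0.5) recover a
    scale-free graph exactly, below 0.2 give a complete graph, above 0.5
    an empty one."""
    from hypercon import synthcohort as sc

    gt = sc.make_powerlaw_ground_truth(300, seed=seed)
    g = sc.gen_s1_network(gt, seed=seed + 1)
    rho = np.where(g.adj, 0.5, 0.2)
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(rho=rho)


class TestThresholdWindow:
    def test_grid_size_matches_printed_grid(self):
        c = _planted_band_matrix()
        w = cn.threshold_window(c, 0.15, 0.65, 0.01, gof_reps=5)
        assert w.grid.size == 51

    def test_degenerate_complete_graph_has_no_window(self):
        rho = np.full((40, 40), 0.9)
        np.fill_diagonal(rho, 1.0)
        w = cn.threshold_window(CorrelationMatrix(rho=rho), 0.15, 0.65, 0.05,
                                gof_reps=10)
        assert w.window is None

    def test_planted_band_contains_midpoint(self):
        c = _planted_band_matrix(seed=21)
        w = cn.threshold_window(c, 0.15, 0.65, 0.05, gof_reps=30, seed=1)
        assert w.window is not None
        lo, hi = w.window
        assert lo <= 0.35 <= hi

    def test_retention_non_increasing_in_threshold(self):
        c = _planted_band_matrix(seed=5)
        w = cn.threshold_window(c, 0.15, 0.65, 0.05, gof_reps=5)
        assert np.all(np.diff(w.retention) <= 1e-12)


def _window_with(grid, lo, hi):
    n = grid.size
    mask = (grid >= lo - 1e-9) & (grid <= hi + 1e-9)
    return cn.ThresholdWindow(
        grid=grid, retention=np.ones(n), scale_free=mask,
        alpha_hat=np.full(n, np.nan), gof_p=np.full(n, np.nan),
        window=(lo, hi),
    )


class TestGroupThreshold:
    grid = np.round(np.arange(0.15, 0.651, 0.01), 10)

    def test_interval_stabbing(self):
        ws = [_window_with(self.grid, 0.30, 0.40),
              _window_with(self.grid, 0.35, 0.45),
              _window_with(self.grid, 0.35, 0.38)]
        assert cn.group_threshold(ws) == pytest.approx(0.38)

    def test_singleton(self):
        assert cn.group_threshold(
            [_window_with(self.grid, 0.36, 0.36)]
        ) == pytest.approx(0.36)

    def test_disjoint_tie_goes_high(self):
        ws = [_window_with(self.grid, 0.2, 0.3), _window_with(self.grid, 0.5, 0.6)]
        assert cn.group_threshold(ws) == pytest.approx(0.6)

    def test_all_empty_errors(self):
        w = _window_with(self.grid, 0.3, 0.3)
        w.window = None
        with pytest.raises(ValueError, match="no subject"):
            cn.group_threshold([w])
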