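import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hypercon import s1h2, synthcohort as sc
from hypercon.connectivity import largest_component
from hypercon.types import BinaryGraph

from conftest import circular_correlation, graph_from_networkx


class TestAngularSeparation:
    def test_antipodal(self):
        assert s1h2.angular_separation(0.0, np.pi) == pytest.approx(np.pi)

    def test_wraparound(self):
        assert s1h2.angular_separation(0.1, 2 * np.pi - 0.1) == pytest.approx(0.2)

    def test_identity(self):
        assert s1h2.angular_separation(1.0, 1.0) == 0.0

    @given(a=st.floats(0, 2 * np.pi), b=st.floats(0, 2 * np.pi))
    @settings(max_examples=50, deadline=None)
    def test_range_and_symmetry(self, a, b):
        d = s1h2.angular_separation(a, b)
        assert 0 <= d <= np.pi + 1e-12
        assert d == pytest.approx(s1h2.angular_separation(b, a))


class TestHyperbolicDistance:
    def test_log_term_vanishes(self):
        assert s1h2.hyperbolic_distance(10, 10, 2.0) == pytest.approx(20.0)

    def test_coincident_angles(self):
        assert s1h2.hyperbolic_distance(10, 10, 0.0) == 0.0
        assert s1h2.hyperbolic_distance(3, 7, 0.0) == pytest.approx(4.0)

    def test_matches_law_of_cosines(self):
        approx = s1h2.hyperbolic_distance(12, 15, 0.05)
        exact = s1h2.hyperbolic_distance(12, 15, 0.05, exact=True)
        assert approx == pytest.approx(exact, abs=0.01)

    @given(
        r1=st.floats(5, 18), r2=st.floats(5, 18),
        dtheta=st.floats(1e-4, 0.2),
    )
    @settings(max_examples=80, deadline=None)
    def test_kernel_consistency_regime(self, r1, r2, dtheta):
        # within 1% where the angular term dominates the |r1 - r2| floor;
        # near the floor the approximation provably degrades (see notes)
        value = r1 + r2 + 2 * np.log(dtheta / 2)
        if value > 10 and value > abs(r1 - r2) + 4:
            approx = s1h2.hyperbolic_distance(r1, r2, dtheta)
            exact = s1h2.hyperbolic_distance(r1, r2, dtheta, exact=True)
            assert abs(approx - exact) / exact < 0.01


class TestConnectionProbability:
    def test_midpoint(self):
        assert s1h2.connection_probability(12.0, 2.5, 12.0) == pytest.approx(0.5)

    def test_saturation(self):
        assert s1h2.connection_probability(1e6, 2.0, 10.0) == pytest.approx(0.0)
        assert s1h2.connection_probability(-1e6, 2.0, 10.0) == pytest.approx(1.0)

    def test_quartile_inversion(self):
        beta, r_hat = 3.0, 14.0
        d = r_hat + (2.0 / beta) * np.log(3.0)
        assert s1h2.connection_probability(d, beta, r_hat) == pytest.approx(0.25)

    def test_rotation_invariance_of_kernel(self):
        # probability of (distance of rotated disc) is unchanged: isometry
        disc = s1h2.to_disc(np.array([3.0, 5.0, 2.0]), np.array([0.1, 2.0, 4.0]),
                            beta=2.5)
        rotated = s1h2.align_disc(disc, [0, 1, 2])
        p1 = s1h2.disc_probability_matrix(disc)
        p2 = s1h2.disc_probability_matrix(rotated)
        assert np.allclose(p1, p2, atol=1e-9)


@pytest.fixture(scope="module")
def s1_draw_200():
    gt = sc.make_powerlaw_ground_truth(200, gamma=2.7, mean_degree=10.0,
                                       beta=2.5, seed=31)
    g = sc.gen_s1_network(gt, seed=32)
    lcc, _ = largest_component(g)
    return lcc


class TestInferBeta:
    def test_recovery_range(self, s1_draw_200):
        beta, warn = s1h2.infer_beta(s1_draw_200, seed=1)
        assert 1.8 <= beta <= 3.3
        assert not warn

    def test_erdos_renyi_pins_low_with_warning(self):
        g = graph_from_networkx(nx.erdos_renyi_graph(250, 0.035, seed=4))
        lcc, _ = largest_component(g)
        beta, warn = s1h2.infer_beta(lcc, seed=2)
        assert beta == pytest.approx(s1h2.BETA_RANGE[0])

    def test_deterministic(self, s1_draw_200):
        a = s1h2.infer_beta(s1_draw_200, seed=7)
        b = s1h2.infer_beta(s1_draw_200, seed=7)
        assert a == b


class TestInferKappa:
    def test_regular_graph_symmetric(self):
        g = graph_from_networkx(nx.circulant_graph(40, [1, 2]))
        kappa = s1h2.infer_kappa(g, beta=2.5)
        assert np.ptp(kappa) / kappa.mean() < 0.01

    def test_ordering_matches_degrees(self, s1_draw_200):
        kappa = s1h2.infer_kappa(s1_draw_200, beta=2.5)
        rho = stats.spearmanr(kappa, s1_draw_200.degrees).statistic
        assert rho >= 0.99

    def test_recovery_against_truth(self, s1_draw_300, request):
        lcc, gt = s1_draw_300
        kappa = s1h2.infer_kappa(lcc, beta=2.5)
        assert np.corrcoef(kappa, gt.kappa)[0, 1] >= 0.9

    def test_bad_beta_rejected(self, s1_draw_200):
        with pytest.raises(ValueError, match="beta"):
            s1h2.infer_kappa(s1_draw_200, beta=1.0)


class TestInferAngles:
    def test_loglik_improves_over_spectral_init(self, s1_draw_200):
        kappa = s1h2.infer_kappa(s1_draw_200, beta=2.5)
        theta0 = s1h2._spectral_angles(s1_draw_200.adj)
        ll0 = s1h2.graph_loglik(s1_draw_200, kappa, theta0, 2.5,
                                s1h2._s1model.mu_from_beta(2.5, s1_draw_200.degrees.mean()))
        theta, ll = s1h2.infer_angles(s1_draw_200, kappa, 2.5, passes=3, seed=0)
        assert ll >= ll0

    def test_deterministic(self, s1_draw_200):
        kappa = s1h2.infer_kappa(s1_draw_200, beta=2.5)
        t1, ll1 = s1h2.infer_angles(s1_draw_200, kappa, 2.5, passes=2, seed=4)
        t2, ll2 = s1h2.infer_angles(s1_draw_200, kappa, 2.5, passes=2, seed=4)
        assert np.array_equal(t1, t2)
        assert ll1 == ll2

    def test_angle_recovery_single_seed(self, embedded_300):
        lcc, gt, disc = embedded_300
        corr = abs(circular_correlation(disc.theta, gt.theta))
        assert corr >= 0.8


class TestToDisc:
    def test_kappa_min_outermost(self):
        kappa = np.array([1.0, 2.0, 8.0])
        disc = s1h2.to_disc(kappa, np.zeros(3), beta=2.5)
        r_disc = 2 * np.log(3 / (disc.mu * np.pi * 1.0**2))
        assert disc.r[0] == pytest.approx(r_disc)
        assert disc.r_hat == pytest.approx(r_disc)

    def test_doubling_kappa_shifts_radius(self):
        kappa = np.array([1.0, 2.0, 4.0])
        disc = s1h2.to_disc(kappa, np.zeros(3), beta=2.5)
        assert disc.r[0] - disc.r[1] == pytest.approx(2 * np.log(2))
        assert disc.r[1] - disc.r[2] == pytest.approx(2 * np.log(2))

    def test_high_degree_nodes_central(self, embedded_300):
        lcc, _, disc = embedded_300
        rho = stats.spearmanr(lcc.degrees, disc.r).statistic
        assert rho <= -0.9

    def test_positive_kappa_required(self):
        with pytest.raises(ValueError, match="positive"):
            s1h2.to_disc(np.array([1.0, -1.0]), np.zeros(2), beta=2.0)


class TestEmbed:
    def test_connected_pairs_closer(self, embedded_300):
        lcc, _, disc = embedded_300
        d = s1h2.disc_distance_matrix(disc)
        iu = np.triu_indices(lcc.n_nodes, 1)
        connected = lcc.adj[iu]
        assert d[iu][connected].mean() < d[iu][~connected].mean()

    def test_deterministic(self, s1_draw_200):
        d1 = s1h2.embed(s1_draw_200, seed=3, beta=2.5)
        d2 = s1h2.embed(s1_draw_200, seed=3, beta=2.5)
        assert np.array_equal(d1.theta, d2.theta)
        assert np.array_equal(d1.r, d2.r)

    def test_too_small_rejected(self):
        g = graph_from_networkx(nx.path_graph(5))
        with pytest.raises(ValueError, match="10 nodes"):
            s1h2.embed(g)

    def test_disconnected_rejected(self):
        g = graph_from_networkx(nx.disjoint_union(nx.path_graph(8),
                                                  nx.path_graph(8)))
        with pytest.raises(ValueError, match="LCC"):
            s1h2.embed(g)


class TestAlignDisc:
    @pytest.fixture()
    def disc(self):
        rng = np.random.default_rng(2)
        kappa = rng.uniform(1, 10, 30)
        theta = rng.uniform(0, 2 * np.pi, 30)
        return s1h2.to_disc(kappa, theta, beta=2.5)

    def test_reference_mean_zero(self, disc):
        refs = [0, 3, 7, 11]
        aligned = s1h2.align_disc(disc, refs)
        z = np.exp(1j * aligned.theta[refs]).mean()
        assert abs(np.angle(z)) < 1e-9

    def test_distances_preserved(self, disc):
        aligned = s1h2.align_disc(disc, [1, 2, 3], reflect=True)
        d0 = s1h2.disc_distance_matrix(disc)
        d1 = s1h2.disc_distance_matrix(aligned)
        assert np.max(np.abs(d0 - d1)) < 1e-12

    def test_idempotent(self, disc):
        once = s1h2.align_disc(disc, [4, 5])
        twice = s1h2.align_disc(once, [4, 5])
        assert np.allclose(once.theta, twice.theta, atol=1e-12)

    def test_empty_reference_rejected(self, disc):
        with pytest.raises(ValueError, match="non-empty"):
            s1h2.align_disc(disc, [])

    def test_degenerate_reference_rejected(self, disc):
        disc.theta[0], disc.theta[1] = 0.0, np.pi
        with pytest.raises(ValueError, match="undefined"):
            s1h2.align_disc(disc, [0, 1])


class TestPermutationEquivariance:
    def test_deterministic_stages_commute(self, s1_draw_200):
        # to_disc and the distance matrix commute with node relabeling
        rng = np.random.default_rng(8)
        kappa = s1h2.infer_kappa(s1_draw_200, beta=2.5)
        theta = s1h2._spectral_angles(s1_draw_200.adj)
        perm = rng.permutation(s1_draw_200.n_nodes)
        d = s1h2.disc_distance_matrix(s1h2.to_disc(kappa, theta, 2.5))
        d_perm = s1h2.disc_distance_matrix(
            s1h2.to_disc(kappa[perm], theta[perm], 2.5)
        )
        assert np.allclose(d_perm, d[np.ix_(perm, perm)], atol=1e-9)
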