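"""RBF network: kernels, density measures, confidence limits, reliability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fermstab import (fit_rbf, fit_reliability_model, input_density,
                      membership_density, predict_with_reliability,
                      query_density, rbf_confidence, stability_surface)
from fermstab.rbf import activations, node_density, predict


def _toy_net(centers, widths, X=None, y=None, **kw):
    """Fit with explicit basis so the geometry is fully controlled."""
    centers = np.asarray(centers, float)
    if X is None:
        X = centers.repeat(3, axis=0)
        X = X + 0.0
    if y is None:
        y = np.zeros(len(X))
    return fit_rbf(X, y, centers=centers, widths=widths, **kw)


class TestActivations:
    def test_unit_at_center_and_closed_form_at_one_sigma(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 2))
        net = fit_rbf(X, rng.normal(size=12), n_hidden=3, seed=0)
        a = activations(net, net.centers * net.x_scales + net.x_means)
        for h in range(3):
            assert a[h, h] == pytest.approx(1.0)
        # query exactly one width away from centre 0 along axis 0
        q = net.centers[0].copy()
        q[0] += net.widths[0]
        a1 = activations(net, q[None] * net.x_scales + net.x_means)[0, 0]
        assert a1 == pytest.approx(np.exp(-0.5), rel=1e-9)

    def test_monotone_decay_along_ray(self):
        net = _toy_net([[0.0, 0.0]], [1.0])
        ray = np.linspace(0, 5, 40)[:, None] * np.array([[1.0, 0.3]])
        a = activations(net, ray * net.x_scales + net.x_means)[:, 0]
        assert np.all(np.diff(a) < 0)

    def test_dimension_mismatch_rejected(self):
        net = _toy_net([[0.0, 0.0]], [1.0])
        with pytest.raises(ValueError):
            activations(net, [[1.0, 2.0, 3.0]])


class TestDensityMeasures:
    """Hand-evaluated oracles for the membership density definitions."""

    def test_symmetric_two_node_three_input_case(self):
        A = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])
        rho = membership_density(A)
        np.testing.assert_allclose(rho, [0.5, 0.5])
        assert query_density([1.0, 0.0], rho) == pytest.approx(0.5)

    def test_asymmetric_case(self):
        # node activations over K=3 inputs: node1 (1,0,0), node2 (1,1,1)
        A = np.array([[1.0, 1.0], [0.0, 1.0], [0.0, 1.0]])
        rho = membership_density(A)
        np.testing.assert_allclose(rho, [1 / 3, 1.0])
        # query x3 with activations (0, 1)
        assert query_density([0.0, 1.0], rho) == pytest.approx(0.75)

    def test_single_node_maximal_membership(self):
        rho = membership_density(np.ones((3, 1)))
        assert rho[0] == pytest.approx(1.0)

    def test_vanishing_activations_vanishing_density(self):
        rho = membership_density(np.full((4, 2), 1e-12))
        assert np.all(rho < 1e-11)

    def test_all_zero_densities_rejected(self):
        with pytest.raises(ValueError):
            query_density([0.5, 0.5], [0.0, 0.0])

    def test_h1_density_equals_activation(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 2))
        net = fit_rbf(X, rng.normal(size=10), n_hidden=1, seed=0)
        q = rng.normal(size=(5, 2))
        np.testing.assert_allclose(input_density(net, q),
                                   activations(net, q)[:, 0], atol=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_densities_bounded_on_random_networks(self, seed):
        """0 <= rho_h <= 1 and 0 <= rho(x) <= 1 for arbitrary geometry."""
        rng = np.random.default_rng(seed)
        n, d, H = rng.integers(6, 20), rng.integers(1, 4), rng.integers(1, 4)
        X = rng.normal(scale=rng.uniform(0.5, 3.0), size=(n, d))
        y = rng.normal(size=n)
        net = fit_rbf(X, y, n_hidden=int(H), seed=int(seed % 1000))
        rho = node_density(net)
        assert np.all((rho >= 0) & (rho <= 1 + 1e-12))
        q = rng.normal(scale=5.0, size=(5, d))
        dens = input_density(net, q)
        assert np.all((dens >= -1e-12) & (dens <= 1 + 1e-12))


class TestFit:
    def test_constant_response(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 2))
        net = fit_rbf(X, np.full(12, 7.5), n_hidden=3, seed=0)
        pred, lo, hi = rbf_confidence(net, X)
        np.testing.assert_allclose(pred, 7.5, atol=1e-8)
        np.testing.assert_allclose(hi - lo, 0.0, atol=1e-6)

    def test_exact_recovery_in_standardized_space(self):
        """With the basis supplied exactly, least squares reproduces the
        generating network to numerical precision."""
        rng = np.random.default_rng(4)
        Z = rng.uniform(-2, 2, size=(50, 2))
        xm, xs = Z.mean(0), Z.std(0, ddof=1)
        Zs = (Z - xm) / xs
        centers = np.array([[-1.0, 0.5], [0.5, -0.5], [1.0, 1.0]])
        widths = np.array([0.7, 0.9, 0.6])
        weights = np.array([1.0, -2.0, 0.8])
        d2 = ((Zs[:, None, :] - centers[None]) ** 2).sum(2)
        y = np.exp(-d2 / (2 * widths**2)) @ weights + 0.1
        net = fit_rbf(Z, y, centers=centers, widths=widths)
        grid = rng.uniform(-1.5, 1.5, size=(80, 2))
        grid_s = (grid - xm) / xs
        d2g = ((grid_s[:, None, :] - centers[None]) ** 2).sum(2)
        truth = np.exp(-d2g / (2 * widths**2)) @ weights + 0.1
        rms = np.sqrt(np.mean((predict(net, grid) - truth) ** 2))
        assert rms < 1e-3

    def test_too_many_nodes_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            fit_rbf(rng.normal(size=(3, 2)), rng.normal(size=3), n_hidden=3)

    def test_coincident_centers_rejected(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="degenerate"):
            fit_rbf(X, rng.normal(size=10),
                    centers=np.zeros((2, 2)), widths=np.array([1.0, 1.0]))

    def test_row_permutation_invariance(self, paper_design):
        X, y = paper_design
        rng = np.random.default_rng(7)
        perm = rng.permutation(len(y))
        net1 = fit_rbf(X, y, n_hidden=3, seed=0)
        net2 = fit_rbf(X[perm], y[perm], n_hidden=3, seed=0)
        q = np.array([[0.05, 4500.0, 33.0]])
        assert predict(net1, q)[0] == pytest.approx(predict(net2, q)[0], rel=1e-6)
        assert input_density(net1, q)[0] == pytest.approx(
            input_density(net2, q)[0], rel=1e-6)


class TestConfidenceLimits:
    def test_band_wider_near_high_residual_cluster(self):
        """Two input clusters, one with far noisier responses: the band at
        the noisy cluster must exceed the band at the quiet one."""
        rng = np.random.default_rng(8)
        quiet = np.column_stack([rng.normal(-3, 0.3, 25), rng.normal(0, 0.3, 25)])
        noisy = np.column_stack([rng.normal(3, 0.3, 25), rng.normal(0, 0.3, 25)])
        X = np.vstack([quiet, noisy])
        y = np.concatenate([rng.normal(0, 0.05, 25), rng.normal(0, 3.0, 25)])
        net = fit_rbf(X, y, n_hidden=2, seed=0)
        _, lo_q, hi_q = rbf_confidence(net, [[-3.0, 0.0]])
        _, lo_n, hi_n = rbf_confidence(net, [[3.0, 0.0]])
        assert hi_n - lo_n > 3 * (hi_q - lo_q)

    def test_monte_carlo_training_coverage(self):
        """Homoscedastic data: the 95% band covers 90-100% of training
        points across replicates."""
        rng = np.random.default_rng(9)
        covs = []
        for _ in range(200):
            X = rng.uniform(-2, 2, size=(40, 2))
            y = np.sin(X[:, 0]) + 0.5 * X[:, 1] + rng.normal(0, 0.3, 40)
            net = fit_rbf(X, y, n_hidden=3, seed=0)
            pred, lo, hi = rbf_confidence(net, X)
            covs.append(np.mean((y >= lo) & (y <= hi)))
        covs = np.array(covs)
        assert 0.90 <= covs.mean() <= 1.00
        assert np.mean(covs >= 0.90) > 0.95


class TestReliability:
    def test_self_coverage_of_training_densities(self, paper_design):
        X, y = paper_design
        net = fit_rbf(X, y, n_hidden=3, seed=0)
        rel = fit_reliability_model(net)
        rho = input_density(net, X)
        _, lo, hi = rel.confidence(X)
        assert np.mean((rho >= lo) & (rho <= hi)) >= 0.95

    def test_constant_density_gives_constant_prediction(self):
        # equilateral training set: by symmetry all densities equal
        X = np.array([[0.0, 0], [1, 0], [0.5, np.sqrt(3) / 2]]).repeat(3, 0)
        X = X + np.random.default_rng(10).normal(0, 1e-3, X.shape)
        net = fit_rbf(X, np.arange(9.0), n_hidden=3, seed=0)
        rel = fit_reliability_model(net)
        pred = rel.predict(X)
        assert np.ptp(pred) < 0.05

    def test_training_point_reliable_far_point_not(self, paper_design):
        X, y = paper_design
        net = fit_rbf(X, y, n_hidden=3, seed=0)
        rel = fit_reliability_model(net)
        at_train = predict_with_reliability(net, rel, X[:1])[0]
        assert at_train.reliable
        span = X.max(0) - X.min(0)
        far = X.mean(0) + 10 * span
        assert not predict_with_reliability(net, rel, far[None])[0].reliable

    def test_bounds_ordering_and_density_fields(self, paper_design):
        X, y = paper_design
        net = fit_rbf(X, y, n_hidden=3, seed=0)
        rel = fit_reliability_model(net)
        for p in predict_with_reliability(net, rel, X[:5]):
            assert p.lower <= p.point <= p.upper
            assert 0.0 <= p.density <= 1.0
            assert 0.0 <= p.density_lower <= p.density_upper <= 1.0


class TestStabilitySurface:
    def test_empty_grid_gives_empty_table(self, paper_design):
        X, y = paper_design
        net = fit_rbf(X, y, n_hidden=3, seed=0)
        rel = fit_reliability_model(net)
        assert stability_surface(net, rel, [], [(0.033, 37.0)]) == []

    def test_cap_bounds_predictions(self, paper_design):
        X, y = paper_design
        net = fit_rbf(X, y, n_hidden=3, seed=0)
        rel = fit_reliability_model(net)
        rows = stability_surface(net, rel, np.arange(3000, 6201, 100),
                                 [(0.033, 37.0), (0.033, 30.0), (0.1, 37.0)],
                                 cap=500.0)
        assert all(r["prediction"] <= 500.0 and r["upper"] <= 500.0 for r in rows)
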