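"""Simulation, lagged covariances and Yule-Walker estimation."""

import numpy as np
import pytest

import mvarnet as mn
from mvarnet.exceptions import ConditioningError, ParameterError, StabilityError
from mvarnet.mvar import load_panel, save_panel
from mvarnet.netgen import ConnectivityMatrix, InputCovariance


def _ar1_conn(a):
    return ConnectivityMatrix(weights=np.array([[a]]), mask=np.array([[a != 0]]))


def _unit_sigma(n):
    return InputCovariance(sigma=np.eye(n), mixing=np.eye(n))


class TestSimulate:
    def test_white_noise_has_no_lag1_autocovariance(self):
        conn = ConnectivityMatrix(weights=np.zeros((4, 4)), mask=np.zeros((4, 4), bool))
        panel = mn.simulate(conn, _unit_sigma(4), 20000, seed=0)
        covs = mn.lagged_covariance(panel, 1)
        t = panel.n_samples
        assert np.abs(np.diag(covs[1])).max() < 4 / np.sqrt(t)

    def test_ar1_stationary_variance(self):
        # var = sigma^2 / (1 - a^2) = 1/(1-0.25)
        panel = mn.simulate(_ar1_conn(0.5), _unit_sigma(1), 100_000, seed=1)
        var = panel.data.var()
        se = np.sqrt(2 / panel.n_samples) * (4 / 3)  # rough se of the variance
        assert abs(var - 4 / 3) < 3 * se * 3  # AR(1) samples are correlated

    def test_same_seed_identical(self, small_net):
        conn, sigma = small_net
        a = mn.simulate(conn, sigma, 500, seed=42)
        b = mn.simulate(conn, sigma, 500, seed=42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_unstable_connectivity_rejected(self):
        with pytest.raises(StabilityError):
            mn.simulate(_ar1_conn(1.1), _unit_sigma(1), 100, seed=0)


class TestLaggedCovariance:
    def test_hand_evaluated_four_point_series(self):
        # x = (1,2,3,4), tau_max=1, mean 2.5, window t=1..3, norm 1/(T-2)=1/2
        panel = mn.TimeSeriesPanel(np.array([[1.0, 2.0, 3.0, 4.0]]))
        covs = mn.lagged_covariance(panel, 1)
        assert covs[0][0, 0] == pytest.approx(1.375)
        assert covs[1][0, 0] == pytest.approx(0.625)

    def test_constant_series_all_zero(self):
        panel = mn.TimeSeriesPanel(np.full((2, 50), 3.0))
        covs = mn.lagged_covariance(panel, 1)
        assert np.abs(covs[0]).max() == 0.0
        assert np.abs(covs[1]).max() == 0.0

    def test_q0_exactly_symmetric(self, small_panel):
        covs = mn.lagged_covariance(small_panel, 2)
        np.testing.assert_array_equal(covs[0], covs[0].T)

    def test_too_short_series_rejected(self):
        with pytest.raises(ParameterError):
            mn.lagged_covariance(mn.TimeSeriesPanel(np.zeros((2, 3))), 2)

    def test_multitrial_matches_concatenation_for_zero_mean_trials(self, small_net):
        conn, sigma = small_net
        trials = np.stack(
            [mn.simulate(conn, sigma, 2000, seed=100 + r).data for r in range(8)]
        )
        multi = mn.lagged_covariance(mn.TimeSeriesPanel(trials), 1)
        concat = mn.lagged_covariance(mn.TimeSeriesPanel(np.concatenate(trials, axis=1)), 1)
        scale = np.abs(concat[0]).max()
        assert np.abs(multi[0] - concat[0]).max() < 0.02 * scale
        assert np.abs(multi[1] - concat[1]).max() < 0.02 * scale


class TestEstimation:
    def test_yule_walker_identity_exact(self, small_net):
        # theoretical Q1 = A Q0, so estimation from theoretical covariances
        # returns A to machine precision
        conn, sigma = small_net
        covs = mn.theoretical_covariance(conn, sigma, 1)
        est = mn.estimate_order1(covs)
        np.testing.assert_allclose(est.a, conn.weights, atol=1e-12)

    def test_consistency_on_simulated_network(self, small_net, small_panel):
        conn, _ = small_net
        est = mn.estimate_order1(mn.lagged_covariance(small_panel, 1))
        assert np.abs(est.a - conn.weights).max() < 0.05

    def test_matches_direct_least_squares(self, small_panel):
        # independent oracle: OLS regression of x^t on x^{t-1} (centered)
        est = mn.estimate_order1(mn.lagged_covariance(small_panel, 1))
        x = small_panel.data
        y = (x[:, 1:] - x[:, 1:].mean(1, keepdims=True)).T
        z = (x[:, :-1] - x[:, :-1].mean(1, keepdims=True)).T
        a_ols = np.linalg.lstsq(z, y, rcond=None)[0].T
        assert np.abs(est.a - a_ols).max() < 10 / small_panel.n_samples

    def test_singular_covariance_raises_conditioning_error(self):
        x = np.random.default_rng(0).standard_normal((1, 200))
        dup = np.vstack([x, x])  # perfectly collinear nodes
        with pytest.raises(ConditioningError):
            mn.estimate_order1(mn.lagged_covariance(mn.TimeSeriesPanel(dup), 1))

    def test_estimation_error_decreases_with_t(self):
        errs = {t: [] for t in (1000, 3000, 10000)}
        for k in range(20):
            conn = mn.generate_connectivity("random", n=15, density=0.3, w_min=0.05, w_max=0.2, seed=400 + k)
            sigma = mn.generate_input_covariance(15, 0.1, seed=400 + k)
            for t in errs:
                panel = mn.simulate(conn, sigma, t, seed=500 + k)
                est = mn.estimate_order1(mn.lagged_covariance(panel, 1))
                errs[t].append(np.abs((est.a - conn.weights)[conn.mask]).mean())
        means = [np.mean(errs[t]) for t in (1000, 3000, 10000)]
        assert means[0] > means[1] > means[2]


class TestOrder2:
    @pytest.fixture(scope="class")
    @staticmethod
    def order2_net():
        conn = mn.generate_connectivity("random", n=8, density=0.3, w_min=0.05, w_max=0.2, seed=77, order=2)
        sigma = mn.generate_input_covariance(8, 0.1, seed=77)
        return conn, sigma

    def test_theoretical_recovery_exact(self, order2_net):
        conn, sigma = order2_net
        covs = mn.theoretical_covariance(conn, sigma, 2)
        est = mn.estimate_order2(covs)
        np.testing.assert_allclose(est.a, conn.weights, atol=1e-10)
        np.testing.assert_allclose(est.a2, conn.weights2, atol=1e-10)

    def test_degenerate_second_order_is_order1(self, small_net):
        # data simulated from an order-1 process: a2 stays below noise floor
        conn, sigma = small_net
        panel = mn.simulate(conn, sigma, 10_000, seed=8)
        est = mn.estimate_order2(mn.lagged_covariance(panel, 2))
        assert np.abs(est.a2).max() < 0.05
        assert np.abs(est.a - conn.weights).max() < 0.05

    def test_matches_stacked_regression(self, order2_net):
        conn, sigma = order2_net
        panel = mn.simulate(conn, sigma, 8000, seed=9)
        est = mn.estimate_order2(mn.lagged_covariance(panel, 2))
        x = panel.data
        y = (x[:, 2:] - x[:, 2:].mean(1, keepdims=True)).T
        z = np.vstack([x[:, 1:-1], x[:, :-2]])
        z = (z - z.mean(1, keepdims=True)).T
        coef = np.linalg.lstsq(z, y, rcond=None)[0].T
        stacked = np.hstack([est.a, est.a2])
        assert np.abs(stacked - coef).max() < 20 / panel.n_samples


class TestTheoreticalCovariance:
    def test_no_coupling_gives_sigma_and_zero_lag1(self):
        conn = ConnectivityMatrix(weights=np.zeros((3, 3)), mask=np.zeros((3, 3), bool))
        sigma = mn.generate_input_covariance(3, 0.4, seed=2)
        covs = mn.theoretical_covariance(conn, sigma, 1)
        np.testing.assert_allclose(covs[0], sigma.sigma, atol=1e-12)
        np.testing.assert_allclose(covs[1], 0, atol=1e-12)

    def test_lag1_identity_holds_exactly(self, small_net):
        conn, sigma = small_net
        covs = mn.theoretical_covariance(conn, sigma, 3)
        np.testing.assert_allclose(covs[1], conn.weights @ covs[0], atol=1e-12)
        np.testing.assert_allclose(covs[3], np.linalg.matrix_power(conn.weights, 3) @ covs[0], atol=1e-12)

    def test_matches_long_simulation(self, small_net):
        conn, sigma = small_net
        panel = mn.simulate(conn, sigma, 400_000, seed=3)
        emp = mn.lagged_covariance(panel, 1)
        theo = mn.theoretical_covariance(conn, sigma, 1)
        scale = np.abs(theo[0]).max()
        assert np.abs(emp[0] - theo[0]).max() < 0.03 * scale
        assert np.abs(emp[1] - theo[1]).max() < 0.03 * scale

    @pytest.mark.parametrize("topology", ["random", "modular", "hierarchical", "ei"])
    def test_oracle_equivalence_all_topologies(self, topology):
        # infinite-T limit: coefficients recovered exactly for every topology
        conn = mn.generate_connectivity(topology, n=10, density=0.3, w_min=0.05, w_max=0.2, seed=31)
        sigma = mn.generate_input_covariance(conn.n_nodes, 0.2, seed=31)
        est = mn.estimate_order1(mn.theoretical_covariance(conn, sigma, 1))
        np.testing.assert_allclose(est.a, conn.weights, atol=1e-10)


def test_panel_tsv_roundtrip(tmp_path, small_panel):
    p = tmp_path / "panel.tsv"
    save_panel(p, small_panel)
    back = load_panel(p)
    np.testing.assert_allclose(back.data, small_panel.data, atol=1e-12)
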