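"""Fully conditional draws checked against independent analytic oracles."""

import numpy as np
import pytest
from scipy import stats

from sbgg.model_core import (
    InvariantViolation,
    ModelState,
    OrdinalDataset,
    make_threshold_vector,
)
from sbgg.gibbs_sampler import (
    _nu_log_weights_grid,
    _u1_log_weights_grid,
    _u2_log_weights_grid,
    griddy_draw,
    nu_log_weight,
    sample_Lambda,
    sample_lambda,
    sample_latents,
    sample_tau_inv,
    sample_theta,
    sample_thresholds,
    u1_log_weight,
    u2_log_weight,
)

N_MC = 20_000  # unit-level Monte-Carlo size; acceptance tests use 1e5


def _state_for(y, gamma, theta, Lam, latent):
    p = theta.size
    return ModelState(
        theta=theta, tau=np.ones(p), lam=np.ones(p), Lam=Lam,
        latent=latent, gamma=gamma, nu=7.0, rho=1.0, delta=1.0,
    )


def _dataset(W, y, k):
    n, p = W.shape
    return OrdinalDataset(
        W=W, y=y, sample_ids=[f"S{i}" for i in range(n)],
        feature_ids=[f"G{j}" for j in range(p)], k=k,
    )


class TestLatentDraws:
    def test_half_line_truncation_mean(self, rng):
        # N(0,1) truncated to (0, inf): mean = phi(0)/(1-Phi(0))
        n = N_MC
        W = np.zeros((n, 1))
        y = np.full(n, 2)
        data = _dataset(W, y, 2)
        state = _state_for(
            y, np.array([-np.inf, 0.0, np.inf]), np.zeros(1), np.ones(n), np.ones(n)
        )
        draws = sample_latents(state, data, rng)
        assert np.all(draws >= 0)
        expected = stats.norm.pdf(0) / stats.norm.sf(0)
        assert draws.mean() == pytest.approx(expected, rel=0.02)

    def test_degenerate_interval_containment(self, rng):
        gamma = make_threshold_vector(np.array([0.0, 1.0, 1.0 + 1e-8]), 4)
        n = 10
        data = _dataset(np.zeros((n, 1)), np.full(n, 3), 4)
        state = _state_for(
            data.y, gamma, np.zeros(1), np.ones(n), np.full(n, 1.0 + 5e-9)
        )
        draws = sample_latents(state, data, rng)
        assert np.all((draws >= 1.0) & (draws < 1.0 + 1e-8))

    def test_respects_category_intervals(self, rng, planted_dataset):
        data, _ = planted_dataset
        gamma = make_threshold_vector(np.array([0.0, 1.0]), 3)
        state = _state_for(
            data.y, gamma, np.zeros(data.p), np.ones(data.n), np.zeros(data.n)
        )
        draws = sample_latents(state, data, rng)
        assert np.all(gamma[data.y - 1] <= draws)
        assert np.all(draws < gamma[data.y])


class TestThetaDraw:
    def _conditioning(self, rng, n=20, p=3):
        W = rng.standard_normal((n, p))
        latent = rng.standard_normal(n)
        return W, latent

    def test_strong_prior_shrinks_mean_to_zero(self, rng):
        W, latent = self._conditioning(rng)
        data = _dataset(W, np.ones(W.shape[0], dtype=int), 2)
        state = _state_for(
            data.y, np.array([-np.inf, 0.0, np.inf]),
            np.zeros(3), np.ones(W.shape[0]), latent,
        )
        state.tau = np.full(3, 1e-12)
        draws = np.array([sample_theta(state, data, rng) for _ in range(200)])
        assert np.max(np.abs(draws.mean(axis=0))) < 1e-4

    def test_flat_prior_mean_is_least_squares(self, rng):
        W, latent = self._conditioning(rng, n=40)
        data = _dataset(W, np.ones(40, dtype=int), 2)
        state = _state_for(
            data.y, np.array([-np.inf, 0.0, np.inf]), np.zeros(3), np.ones(40), latent
        )
        state.tau = np.full(3, 1e12)  # T* -> 0
        draws = np.array([sample_theta(state, data, rng) for _ in range(4000)])
        ls, *_ = np.linalg.lstsq(W, latent, rcond=None)
        se = draws.std(axis=0) / np.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - ls) < 4 * se)

    def test_moments_match_analytic_gaussian(self, rng):
        W, latent = self._conditioning(rng, n=15)
        Lam = rng.gamma(2.0, 1.0, size=15)
        tau = rng.gamma(2.0, 1.0, size=3)
        data = _dataset(W, np.ones(15, dtype=int), 2)
        state = _state_for(
            data.y, np.array([-np.inf, 0.0, np.inf]), np.zeros(3), Lam, latent
        )
        state.tau = tau
        P = (W.T * Lam) @ W + np.diag(1.0 / tau)
        cov = np.linalg.inv(P)
        mean = cov @ (W.T * Lam) @ latent
        draws = np.array([sample_theta(state, data, rng) for _ in range(N_MC)])
        se_mean = np.sqrt(np.diag(cov) / N_MC)
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 3.5 * se_mean)
        emp_cov = np.cov(draws.T)
        se_cov = np.sqrt(
            (np.outer(np.diag(cov), np.diag(cov)) + cov**2) / N_MC
        )
        assert np.all(np.abs(emp_cov - cov) < 3.5 * se_cov)


class TestScaleDraws:
    def test_tau_inv_positive_and_mean(self, rng):
        draws = sample_tau_inv(
            np.full(N_MC, 1.0), np.full(N_MC, 2.0), rng
        )
        assert np.all(draws > 0)
        # inverse-Gaussian mean lam/|theta| = 2
        assert draws.mean() == pytest.approx(2.0, rel=0.02)

    def test_tau_inv_zero_theta_guard(self, rng):
        draws = sample_tau_inv(np.zeros(100), np.ones(100), rng)
        assert np.all(np.isfinite(draws)) and np.all(draws > 0)

    def test_lambda_mean_and_variance(self, rng):
        draws = sample_lambda(np.zeros(N_MC), 1.0, 1.0, rng)
        assert np.all(draws > 0)
        assert draws.mean() == pytest.approx(2.0, rel=0.02)  # (rho+1)/(|t|+delta)
        draws = sample_lambda(np.full(N_MC * 5, 1.5), 2.0, 0.5, rng)
        assert draws.var() == pytest.approx(3.0 / 4.0, rel=0.05)  # 3/(2)^2

    def test_Lambda_means(self, rng):
        draws = sample_Lambda(np.zeros(N_MC), 1.0, rng)
        assert np.all(draws > 0)
        assert draws.mean() == pytest.approx(2.0, rel=0.02)  # Gamma(1, 1/2)
        draws = sample_Lambda(np.full(N_MC, 2.0), 3.0, rng)
        assert draws.mean() == pytest.approx(4.0 / 7.0, rel=0.02)


class TestGriddy:
    def test_single_point_forced(self, rng):
        for _ in range(5):
            assert griddy_draw([2.5], [0.0], rng) == 2.5

    def test_equal_weights_uniform_frequencies(self, rng):
        draws = np.array(
            [griddy_draw([1, 2, 3, 4], np.full(4, -3.7), rng) for _ in range(N_MC)]
        )
        se = np.sqrt(0.25 * 0.75 / N_MC)
        for v in (1, 2, 3, 4):
            assert abs(np.mean(draws == v) - 0.25) < 3 * se

    def test_log_weight_normalization(self, rng):
        lw = np.log([1.0, 3.0])
        draws = np.array([griddy_draw([0, 1], lw, rng) for _ in range(N_MC)])
        se = np.sqrt(0.75 * 0.25 / N_MC)
        assert abs(draws.mean() - 0.75) < 3 * se

    def test_rejects_all_zero_weights(self, rng):
        with pytest.raises(ValueError):
            griddy_draw([1.0, 2.0], [-np.inf, -np.inf], rng)

    def test_max_subtraction_handles_huge_weights(self, rng):
        # would overflow a naive exp
        val = griddy_draw([1.0, 2.0], [5000.0, 5000.0 + np.log(3)], rng)
        assert val in (1.0, 2.0)


class TestGriddyWeights:
    def test_nu_hand_value(self):
        assert nu_log_weight(2.0, np.array([1.0])) == pytest.approx(-1.0, abs=1e-12)

    def test_nu_no_overflow_large_df(self):
        Lam = np.random.default_rng(0).gamma(2.0, 1.0, size=100)
        assert np.isfinite(nu_log_weight(1000.0, Lam))

    def test_nu_ratio_matches_product_form(self, rng):
        from scipy.special import gamma as G

        Lam = rng.gamma(2.0, 1.0, size=3)

        def brute(nu):  # direct product-form oracle, no logs
            return float(
                np.prod(Lam ** (nu / 2 - 1) * np.exp(-nu * Lam / 2))
                * ((nu / 2) ** (nu / 2) / G(nu / 2)) ** Lam.size
            )

        log_ratio = nu_log_weight(5.0, Lam) - nu_log_weight(3.0, Lam)
        assert log_ratio == pytest.approx(np.log(brute(5.0) / brute(3.0)), abs=1e-10)

    def test_u1_zero_at_unit_rho_with_null_theta(self):
        c = 2.0
        assert u1_log_weight(1.0 / (1.0 + c), np.zeros(1), delta=0.7, c=c) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_u_transform_mappings(self):
        from sbgg.gibbs_sampler import delta_from_u2, rho_from_u1

        assert rho_from_u1(0.5, 1.0) == pytest.approx(1.0)
        assert rho_from_u1(0.2, 1.0) == pytest.approx(4.0)
        assert delta_from_u2(0.5, 1.0) == pytest.approx(1.0)

    def test_u_weight_ratios_match_product_form(self, rng):
        theta = rng.normal(0, 2, size=3)
        c, cp, rho, delta = 1.3, 0.8, 2.0, 0.6

        def brute_u1(u1):
            r = (1 - u1) / (c * u1)
            return float(r ** theta.size * np.prod((1 + np.abs(theta) / delta) ** (-(r + 1))))

        def brute_u2(u2):
            inv_d = cp * u2 / (1 - u2)
            return float(
                inv_d ** theta.size * np.prod((1 + inv_d * np.abs(theta)) ** (-(1 + rho)))
            )

        lr = u1_log_weight(0.6, theta, delta, c) - u1_log_weight(0.3, theta, delta, c)
        assert lr == pytest.approx(np.log(brute_u1(0.6) / brute_u1(0.3)), abs=1e-10)
        lr = u2_log_weight(0.7, theta, rho, cp) - u2_log_weight(0.2, theta, rho, cp)
        assert lr == pytest.approx(np.log(brute_u2(0.7) / brute_u2(0.2)), abs=1e-10)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
    def test_u_weights_reject_boundary(self, bad):
        with pytest.raises(ValueError):
            u1_log_weight(bad, np.zeros(2), 1.0, 1.0)
        with pytest.raises(ValueError):
            u2_log_weight(bad, np.zeros(2), 1.0, 1.0)

    def test_grid_helpers_match_scalar_ops(self, rng):
        theta = rng.normal(0, 1, size=4)
        Lam = rng.gamma(2.0, 1.0, size=6)
        u_grid = np.linspace(0.05, 0.95, 19)
        nu_grid = np.array([1.0, 3.0, 7.0, 30.0])
        np.testing.assert_allclose(
            _nu_log_weights_grid(nu_grid, Lam),
            [nu_log_weight(v, Lam) for v in nu_grid],
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            _u1_log_weights_grid(u_grid, theta, 0.9, 1.2),
            [u1_log_weight(u, theta, 0.9, 1.2) for u in u_grid],
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            _u2_log_weights_grid(u_grid, theta, 1.7, 0.5),
            [u2_log_weight(u, theta, 1.7, 0.5) for u in u_grid],
            rtol=1e-12,
        )


class TestThresholdDraw:
    def _setup(self, latents, y, gamma, k=4, n_extra=0):
        n = len(y)
        data = _dataset(np.zeros((n, 1)), np.asarray(y), k)
        state = _state_for(
            data.y, gamma, np.zeros(1), np.ones(n), np.asarray(latents, dtype=float)
        )
        return state, data

    def test_bounds_from_neighbouring_latents(self, rng):
        gamma = make_threshold_vector(np.array([0.0, 0.9, 2.0]), 4)
        state, data = self._setup(
            [0.3, 0.8, 1.1, 1.5, 2.2], [2, 2, 3, 3, 4], gamma
        )
        draws = np.array(
            [sample_thresholds(state, data, rng)[2] for _ in range(2000)]
        )
        assert np.all((draws > 0.8) & (draws < 1.1))
        assert draws.mean() == pytest.approx((0.8 + 1.1) / 2, rel=0.02)

    def test_output_non_decreasing(self, rng, planted_dataset):
        data, truth = planted_dataset
        state = _state_for(
            data.y, truth.gamma_true.copy(), np.zeros(data.p),
            np.ones(data.n), data.W @ truth.theta_true,
        )
        # regenerate latents consistent with thresholds before updating them
        state.gamma = make_threshold_vector(
            truth.gamma_true[1:-1] - truth.gamma_true[1], data.k
        )
        state.latent = sample_latents(state, data, rng)
        for _ in range(50):
            state.gamma = sample_thresholds(state, data, rng)
            assert np.all(np.diff(state.gamma[1:-1]) >= 0)

    def test_empty_category_falls_back_to_neighbours(self, rng):
        gamma = make_threshold_vector(np.array([0.0, 1.0, 2.0]), 4)
        # no samples in category 3: gamma_4's interval is (gamma_3, min l|y=4)
        state, data = self._setup([0.5, 2.5], [2, 4], gamma)
        for _ in range(200):
            g = sample_thresholds(state, data, rng)
            # gamma_3 bounded by (max l|y=2, old gamma_4); gamma_4 by (new gamma_3, min l|y=4)
            assert 0.5 <= g[2] <= 2.0
            assert g[2] <= g[3] <= 2.5

    def test_inconsistent_latents_raise(self, rng):
        gamma = make_threshold_vector(np.array([0.0, 1.0, 2.0]), 4)
        state, data = self._setup([1.8, 1.2], [2, 3], gamma)  # y=2 latent above y=3's
        with pytest.raises(InvariantViolation):
            sample_thresholds(state, data, rng)
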