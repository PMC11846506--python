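"""Forecasting, impulse responses, contrasts, conditional lag functions.

Posterior-draw containers are fabricated directly where closed forms
exist, so these checks are independent of the sampler.
"""

import numpy as np
import pytest

from gamvar import dynamics, scenario
from gamvar.inference import PosteriorDraws


def make_draws(
    a, A, sigma, C, T=40, n_draws=30, b=None, z_last=None, species=None
):
    a = np.asarray(a, dtype=float)
    n = a.size
    A = np.asarray(A, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    C = np.asarray(C, dtype=float)
    z = np.zeros((n, T))
    if z_last is not None:
        z[:, -1] = z_last
    mu = np.tile(a[:, None], (1, T))
    params = {
        "a": np.tile(a, (1, n_draws, 1)),
        "sigma": np.tile(sigma, (1, n_draws, 1)),
        "A": np.tile(A, (1, n_draws, 1, 1)),
        "C": np.tile(C, (1, n_draws, 1, 1)),
        "z": np.tile(z, (1, n_draws, 1, 1)),
        "mu": np.tile(mu, (1, n_draws, 1, 1)),
        "X": np.tile(mu + z, (1, n_draws, 1, 1)),
    }
    if b is not None:
        params["b"] = np.tile(np.asarray(b, dtype=float), (1, n_draws, 1))
    return PosteriorDraws(
        params=params,
        species_ids=species or [f"s{i}" for i in range(n)],
        variant="GAM-VAR",
    )


class TestForecast:
    def test_intercept_only_forecast_mean(self, small_model_data):
        # A = 0, sigma -> 0: predictive mean is exp(intercept) at all steps
        data = small_model_data
        n = data.n_species
        T = data.T - 12
        draws = make_draws(
            a=np.log(4.0) * np.ones(n),
            A=np.zeros((n, n)),
            sigma=np.full(n, 1e-8),
            C=np.eye(n),
            T=T,
            n_draws=400,
        )
        ens = scenario.forecast(draws, data, horizon=12, seed=0, max_draws=400)
        assert ens.counts.shape == (400, 12, n)
        assert np.allclose(ens.counts.mean(axis=0), 4.0, atol=0.5)

    def test_horizon_must_fit_covariates(self, small_model_data):
        data = small_model_data
        draws = make_draws(
            a=np.zeros(data.n_species),
            A=np.zeros((data.n_species, data.n_species)),
            sigma=np.ones(data.n_species),
            C=np.eye(data.n_species),
            T=data.T,
        )
        with pytest.raises(ValueError):
            scenario.forecast(draws, data, horizon=1)

    def test_forecast_variance_bounded_by_stationary(self, small_model_data):
        data = small_model_data
        n = data.n_species
        rng = np.random.default_rng(0)
        sigma = np.full(n, 0.4)
        C = np.eye(n)
        Sigma = np.diag(sigma**2)
        A = dynamics.map_to_stationary(rng.normal(scale=1.2, size=(n, n)), Sigma)
        G = dynamics.stationary_covariance(A, Sigma)
        # start draws at deviations sampled from the stationary law
        draws = make_draws(
            a=np.zeros(n), A=A, sigma=sigma, C=C, T=data.T - 12, n_draws=600
        )
        zs = np.linalg.cholesky(G) @ rng.standard_normal((n, 600))
        draws.params["z"][0, :, :, -1] = zs.T
        ens = scenario.forecast(draws, data, horizon=12, seed=1, max_draws=600)
        dev = ens.latent[:, -1, :] - ens.mu[:, -1, :]
        assert np.all(dev.var(axis=0) <= 1.35 * np.diag(G))


class TestImpulseResponse:
    def test_zero_impulse_is_identically_zero(self):
        draws = make_draws(
            a=np.log(3.0) * np.ones(3),
            A=0.5 * np.eye(3),
            sigma=np.ones(3),
            C=np.eye(3),
        )
        out = scenario.impulse_response(draws, "s0", extra_captures=0.0)
        assert np.all(out.responses == 0.0)

    def test_diagonal_propagation_closed_form(self):
        # A = 0.5 I, Sigma = I: own response halves each month, no spillover
        a = np.log(np.array([5.0, 2.0]))
        draws = make_draws(a=a, A=0.5 * np.eye(2), sigma=np.ones(2), C=np.eye(2))
        out = scenario.impulse_response(draws, "s0", extra_captures=3.0, horizon=6)
        delta0 = np.log(5.0 + 3.0) - np.log(5.0)
        med = out.median()
        for h in range(7):
            assert med[h, 0] == pytest.approx(0.5**h * delta0, rel=1e-10)
            assert med[h, 1] == pytest.approx(0.0, abs=1e-12)

    def test_correlated_errors_spill_contemporaneously(self):
        # corr = 0.6, A = 0: horizon-0 spillover 0.6 * delta * s2/s1, gone at h=1
        s = np.array([1.0, 2.0])
        C = np.array([[1.0, 0.6], [0.6, 1.0]])
        a = np.log(np.array([4.0, 4.0]))
        draws = make_draws(a=a, A=np.zeros((2, 2)), sigma=s, C=C)
        out = scenario.impulse_response(draws, "s0", extra_captures=3.0, horizon=3)
        delta0 = np.log(7.0) - np.log(4.0)
        med = out.median()
        assert med[0, 1] == pytest.approx(0.6 * delta0 * (s[1] / s[0]), rel=1e-10)
        assert np.allclose(med[1:], 0.0, atol=1e-12)

    def test_unknown_species_rejected(self):
        draws = make_draws(a=[0.0], A=[[0.2]], sigma=[1.0], C=[[1.0]])
        with pytest.raises(ValueError):
            scenario.impulse_response(draws, "nope")

    def test_matches_noisefree_state_simulation(self):
        # closed-form A^h delta equals propagating the perturbed state
        rng = np.random.default_rng(5)
        n = 3
        sigma = rng.uniform(0.3, 0.8, n)
        C = np.eye(n)
        A = dynamics.map_to_stationary(rng.normal(size=(n, n)), np.diag(sigma**2))
        draws = make_draws(a=np.log(3.0) * np.ones(n), A=A, sigma=sigma, C=C)
        out = scenario.impulse_response(draws, "s1", extra_captures=3.0, horizon=6)
        delta = out.responses[0, 0]
        path = delta.copy()
        for h in range(1, 7):
            path = A @ path
            assert np.allclose(out.responses[0, h], path, atol=1e-12)


class TestCovariateContrast:
    def test_zero_slope_gives_zero_delta(self, small_model_data):
        draws = make_draws(
            a=np.zeros(4), A=np.zeros((4, 4)), sigma=np.ones(4), C=np.eye(4),
            b=np.zeros(4), T=small_model_data.T,
        )
        delta, p_le, p_gt = scenario.covariate_contrast(draws, small_model_data)
        assert np.allclose(delta, 0.0)

    def test_fixed_slope_closed_form(self, small_model_data):
        # slope 0.4 over a 1.0 z-unit contrast at mu_ref = 0:
        # exp(0.2) - exp(-0.2) around exp(0) -> delta = 2 sinh(0.2)
        draws = make_draws(
            a=np.zeros(4), A=np.zeros((4, 4)), sigma=np.ones(4), C=np.eye(4),
            b=0.4 * np.ones(4), T=small_model_data.T,
        )
        delta, _, p_gt = scenario.covariate_contrast(draws, small_model_data)
        assert np.allclose(delta, np.exp(0.2) - np.exp(-0.2), atol=1e-12)
        assert np.allclose(p_gt, 1.0)

    def test_sign_proportions_sum_to_one(self, small_model_data, rng):
        draws = make_draws(
            a=np.zeros(4), A=np.zeros((4, 4)), sigma=np.ones(4), C=np.eye(4),
            b=np.zeros(4), T=small_model_data.T, n_draws=200,
        )
        draws.params["b"] = rng.normal(0.0, 1.0, size=draws.params["b"].shape)
        delta, p_le, p_gt = scenario.covariate_contrast(draws, small_model_data)
        assert np.allclose(p_le + p_gt, 1.0)
        assert np.all((0.2 < p_gt) & (p_gt < 0.8))  # centred slopes: ~50/50

    def test_variant_without_ndvi_rejected(self, small_model_data):
        draws = make_draws(
            a=np.zeros(4), A=np.zeros((4, 4)), sigma=np.ones(4), C=np.eye(4),
            T=small_model_data.T,
        )
        with pytest.raises(ValueError):
            scenario.covariate_contrast(draws, small_model_data)


class TestConditionalLagFunction:
    YEAR = np.array([2.0, 3, 6, 11, 16, 21, 25, 24, 20, 14, 8, 3])

    def _draws_with_smooth(self, data, coef_scale=1.0, n_draws=40, dev=None):
        p = data.Xg_full.shape[1]
        rng = np.random.default_rng(9)
        draws = make_draws(
            a=np.zeros(4), A=np.zeros((4, 4)), sigma=np.ones(4), C=np.eye(4),
            T=data.T, n_draws=n_draws,
        )
        draws.params["beta_g"] = coef_scale * rng.standard_normal((1, n_draws, p))
        if dev is not None:
            draws.dev_species = [dev]
            draws.params[f"beta_dev:{dev}"] = rng.standard_normal((1, n_draws, p))
        return draws

    def test_zero_coefficients_flat_with_warning(self, small_model_data):
        draws = self._draws_with_smooth(small_model_data, coef_scale=0.0)
        with pytest.warns(RuntimeWarning):
            curves = scenario.conditional_lag_function(
                draws, small_model_data, self.YEAR, n_functions=20
            )
        assert np.allclose(curves["s0"], 0.0)

    def test_species_outside_subset_gets_global_curve(self, small_model_data):
        draws = self._draws_with_smooth(small_model_data, dev="s0")
        curves = scenario.conditional_lag_function(
            draws, small_model_data, self.YEAR, n_functions=30, seed=3
        )
        # s1 and s2 share the global function; matched draws agree exactly
        assert np.allclose(curves["s1"], curves["s2"])
        assert not np.allclose(curves["s0"], curves["s1"])

    def test_requested_number_of_functions(self, small_model_data):
        draws = self._draws_with_smooth(small_model_data)
        curves = scenario.conditional_lag_function(
            draws, small_model_data, self.YEAR, n_functions=1000
        )
        assert curves["s0"].shape == (1000, 12)

    def test_curves_scaled_to_unit_variance(self, small_model_data):
        draws = self._draws_with_smooth(small_model_data)
        curves = scenario.conditional_lag_function(
            draws, small_model_data, self.YEAR, n_functions=50
        )
        assert np.allclose(curves["s0"].std(axis=1), 1.0, atol=1e-8)
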