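"""Penalized bases: cubic and thin-plate marginals, tensor products,
distributed-lag summation, constraints, hierarchical sets."""

import numpy as np
import pytest

from gamvar import smooths
from gamvar.preprocess import LagDesign


@pytest.fixture(scope="module")
def xgrid():
    return np.linspace(0.0, 6.0, 80)


class TestCubicBasis:
    def test_dimensions(self, xgrid):
        d = smooths.cubic_basis(xgrid, k=4)
        assert d.X.shape == (80, 4)
        assert d.penalties[0].shape == (4, 4)
        assert d.nullspace_dim == 2

    def test_linear_function_in_span_with_zero_penalty(self, xgrid):
        d = smooths.cubic_basis(xgrid, k=5)
        knots = np.quantile(np.unique(xgrid), np.linspace(0, 1, 5))
        beta = 2.0 * knots - 1.0  # cardinal basis: coefs are knot values
        assert np.allclose(d.X @ beta, 2.0 * xgrid - 1.0, atol=1e-10)
        assert beta @ d.penalties[0] @ beta == pytest.approx(0.0, abs=1e-10)

    def test_wiggly_function_is_penalized(self, xgrid):
        d = smooths.cubic_basis(xgrid, k=6)
        beta, *_ = np.linalg.lstsq(d.X, np.sin(xgrid), rcond=None)
        assert beta @ d.penalties[0] @ beta > 0.0

    def test_penalty_is_psd(self, xgrid):
        d = smooths.cubic_basis(xgrid, k=6)
        assert np.linalg.eigvalsh(d.penalties[0]).min() > -1e-10

    def test_penalty_matches_quadrature(self, xgrid):
        # curvature penalty equals the integrated squared second derivative
        d = smooths.cubic_basis(xgrid, k=4)
        rng = np.random.default_rng(0)
        beta = rng.normal(size=4)
        fine = np.linspace(0.0, 6.0, 4001)
        f = d.evaluate(fine) @ beta
        f2 = np.gradient(np.gradient(f, fine), fine)
        quad = np.trapezoid(f2[5:-5] ** 2, fine[5:-5])
        assert beta @ d.penalties[0] @ beta == pytest.approx(quad, rel=0.02)

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            smooths.cubic_basis(np.array([1.0, 1.0, 2.0]), k=4)


class TestThinPlateBasis:
    def test_dimensions(self, rng):
        d = smooths.thin_plate_basis(rng.normal(size=100), k=3)
        assert d.X.shape[1] == 3

    def test_constant_unpenalized(self, rng):
        d = smooths.thin_plate_basis(rng.normal(size=100), k=3)
        beta = np.array([1.0, 0.0, 0.0])  # constant column
        assert beta @ d.penalties[0] @ beta == pytest.approx(0.0, abs=1e-12)

    def test_fits_wiggly_target_better_than_polynomial(self, rng):
        x = np.linspace(-2, 2, 120)
        y = np.sin(3 * x)
        d = smooths.thin_plate_basis(x, k=5)
        fit_res = np.linalg.lstsq(d.X, y, rcond=None)[1]
        P = np.vander(x, 5)
        poly_res = np.linalg.lstsq(P, y, rcond=None)[1]
        assert fit_res[0] < poly_res[0]


@pytest.fixture(scope="module")
def tensor():
    rng = np.random.default_rng(1)
    lags = np.tile(np.arange(7.0), 40)
    temps = rng.normal(size=280)
    bl = smooths.cubic_basis(lags, k=4)
    bt = smooths.thin_plate_basis(temps, k=3)
    return smooths.tensor_product(bl, bt)


class TestTensorProduct:
    def test_dimensions_and_penalty_count(self, tensor):
        assert tensor.X.shape[1] == 12
        assert len(tensor.penalties) == 2

    def test_constant_function_unpenalized_both_margins(self, tensor):
        # constant = (constant in lag) x (constant in temp); find it by
        # solving for coefficients reproducing 1 everywhere
        beta, *_ = np.linalg.lstsq(tensor.X, np.ones(tensor.X.shape[0]), rcond=None)
        for S in tensor.penalties:
            assert beta @ S @ beta == pytest.approx(0.0, abs=1e-8)

    def test_separable_function_penalized_in_one_margin(self, tensor):
        # coefficients constant in lag (cardinal cubic basis: all ones)
        # times a wiggly temperature profile: only the temperature margin
        # should be penalized
        rng = np.random.default_rng(2)
        c_temp = rng.normal(size=3)
        c_temp[2] = 1.5  # ensure mass on the penalized radial direction
        beta = np.kron(np.ones(4), c_temp)
        S_lag, S_temp = tensor.penalties
        assert beta @ S_temp @ beta > 1e-4
        assert beta @ S_lag @ beta == pytest.approx(0.0, abs=1e-8)

    def test_shape_mismatch_errors(self):
        b1 = smooths.cubic_basis(np.linspace(0, 6, 30), k=4)
        b2 = smooths.thin_plate_basis(np.linspace(0, 1, 40), k=3)
        with pytest.raises(ValueError):
            smooths.tensor_product(b1, b2)


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(3)
    T, L = 50, 6
    x = rng.normal(size=T + L)
    ld = LagDesign(
        value_matrix=np.column_stack([x[L - l : L - l + T] for l in range(L + 1)])
    )
    lags = ld.lag_matrix.ravel()
    temps = ld.value_matrix.ravel()
    bl = smooths.cubic_basis(lags, k=4)
    bt = smooths.thin_plate_basis(temps, k=3)
    tensor_ = smooths.tensor_product(bl, bt)
    return tensor_, ld


class TestDistributedLag:
    def test_matches_bruteforce_per_lag_sum(self, setup):
        tensor, ld = setup
        dl = smooths.distributed_lag_design(tensor, ld)
        T, L1 = ld.value_matrix.shape
        brute = np.zeros_like(dl.X)
        for t in range(T):
            for l in range(L1):
                brute[t] += tensor.evaluate(
                    np.array([float(l)]), ld.value_matrix[t, l : l + 1]
                )[0]
        assert np.abs(dl.X - brute).max() < 1e-10

    def test_zero_lag_reduces_to_plain_tensor(self, setup):
        tensor, ld = setup
        ld0 = LagDesign(value_matrix=ld.value_matrix[:, :1])
        dl = smooths.distributed_lag_design(tensor, ld0)
        direct = tensor.evaluate(np.zeros(ld0.value_matrix.shape[0]), ld0.value_matrix[:, 0])
        assert np.allclose(dl.X, direct)

    def test_zero_coefficients_contribute_nothing(self, setup):
        tensor, ld = setup
        dl = smooths.distributed_lag_design(tensor, ld)
        assert np.allclose(dl.X @ np.zeros(dl.n_coef), 0.0)

    def test_penalties_inherited(self, setup):
        tensor, ld = setup
        dl = smooths.distributed_lag_design(tensor, ld)
        assert len(dl.penalties) == 2
        for Sd, St in zip(dl.penalties, tensor.penalties):
            assert np.allclose(Sd, St)


@pytest.fixture(scope="module")
def dl():
    rng = np.random.default_rng(4)
    x = rng.normal(size=60)
    ld = LagDesign(
        value_matrix=np.column_stack([np.roll(x, l)[6:] for l in range(7)])
    )
    return smooths.build_distributed_lag_smooth(ld)


class TestConstraintAndHierarchy:
    def test_sum_to_zero_columns(self, dl):
        assert np.abs(dl.X.sum(axis=0)).max() < 1e-8

    def test_penalties_stay_psd(self, dl):
        for S in dl.penalties:
            assert np.linalg.eigvalsh(S).min() > -1e-8

    def test_hierarchical_counts(self, dl):
        hs = smooths.make_hierarchical(dl, ["a", "b", "c", "d"], species_ids=list("abcdefghi"))
        assert len(hs.deviations) == 4
        assert hs.global_design is dl

    def test_unknown_species_rejected(self, dl):
        with pytest.raises(ValueError):
            smooths.make_hierarchical(dl, ["nope"], species_ids=["a", "b"])

    def test_deviation_fully_penalized(self, dl):
        hs = smooths.make_hierarchical(dl, ["a"], species_ids=["a"])
        dev = hs.deviations["a"]
        total = np.sum(dev.penalties, axis=0)
        assert np.linalg.eigvalsh(total).min() > 1e-10  # no unpenalized direction
        rng = np.random.default_rng(5)
        for _ in range(20):
            beta = rng.normal(size=dev.n_coef)
            assert beta @ total @ beta > 0.0

    def test_zero_deviation_collapses_to_global(self, dl):
        hs = smooths.make_hierarchical(dl, ["a"], species_ids=["a"])
        beta_g = np.random.default_rng(6).normal(size=dl.n_coef)
        combined = hs.global_design.X @ beta_g + hs.deviations["a"].X @ np.zeros(dl.n_coef)
        assert np.allclose(combined, dl.X @ beta_g)


class TestAffineInvariance:
    def test_predictions_invariant_to_covariate_rescaling(self):
        # knots sit at quantiles, so an affine map of the covariate produces
        # an equivalent basis: fitted values of a smooth target must agree
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, 150)
        y = np.sin(6 * x) + 0.1 * rng.normal(size=150)
        preds = []
        for scale, shift in [(1.0, 0.0), (12.0, -3.0)]:
            d = smooths.cubic_basis(scale * x + shift, k=6)
            beta, *_ = np.linalg.lstsq(d.X, y, rcond=None)
            preds.append(d.X @ beta)
        assert np.allclose(preds[0], preds[1], atol=1e-8)
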