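import numpy as np
import pytest
from sklearn.base import clone

from gwrshift.sar import (SpatialLagRegressor, _lag_eigenvalues, fit_sar_lag,
                          log_det_from_eigenvalues)
from gwrshift.spatial_weights import KernelSpec, SpatialWeights, build_weights

import pandas as pd


def rook_lattice_weights(side):
    """Row-standardized rook-contiguity weights on a side x side lattice."""
    n = side * side
    w = np.zeros((n, n))
    for r in range(side):
        for c in range(side):
            i = r * side + c
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < side and 0 <= cc < side:
                    w[i, rr * side + cc] = 1.0
    return w


def simulate_lag(rng, W_rs, rho, beta, sigma=1.0):
    n = W_rs.shape[0]
    x = rng.standard_normal(n)
    eps = sigma * rng.standard_normal(n)
    y = np.linalg.solve(np.eye(n) - rho * W_rs, beta[0] + beta[1] * x + eps)
    return x, y


class TestLogDeterminant:
    @pytest.mark.parametrize("rho", [-0.5, 0.0, 0.5, 0.9])
    def test_eigenvalue_logdet_matches_dense(self, rho):
        raw = rook_lattice_weights(5)  # n = 25
        W = raw / raw.sum(axis=1)[:, None]
        lam = _lag_eigenvalues(W, assume_similar_symmetric=True)
        dense = np.linalg.slogdet(np.eye(25) - rho * W)[1]
        assert log_det_from_eigenvalues(rho, lam) == pytest.approx(dense, abs=1e-9)


class TestEstimation:
    def test_rho_zero_data_reduce_to_ols(self):
        rng = np.random.default_rng(0)
        raw = rook_lattice_weights(10)
        W = raw / raw.sum(axis=1)[:, None]
        rhos = []
        for _ in range(10):
            x, y = simulate_lag(rng, W, rho=0.0, beta=np.array([1.0, 0.5]))
            fit = fit_sar_lag(y, x[:, None], W, row_standardize=False)
            rhos.append(fit.rho_)
            Xd = np.column_stack([np.ones(100), x])
            beta_ols = np.linalg.lstsq(Xd, y, rcond=None)[0]
            assert abs(fit.coef_[0] - beta_ols[1]) < 2 * fit.se_[1]
        assert abs(np.mean(rhos)) < 0.12

    def test_parameter_recovery_on_lattice(self):
        rng = np.random.default_rng(1)
        raw = rook_lattice_weights(12)
        W = raw / raw.sum(axis=1)[:, None]
        est = SpatialLagRegressor(weights=W, row_standardize=False)
        rhos, slopes = [], []
        for _ in range(25):
            x, y = simulate_lag(rng, W, rho=0.6, beta=np.array([1.0, 0.5]))
            fit = clone(est).set_params(weights=W).fit(x[:, None], y)
            rhos.append(fit.rho_)
            slopes.append(fit.coef_[0])
        assert np.mean(rhos) == pytest.approx(0.6, abs=0.1)
        assert np.mean(slopes) == pytest.approx(0.5, abs=0.08)

    def test_loglik_at_optimum_beats_rho_zero(self):
        rng = np.random.default_rng(2)
        raw = rook_lattice_weights(8)
        W = raw / raw.sum(axis=1)[:, None]
        x, y = simulate_lag(rng, W, rho=0.7, beta=np.array([0.0, 1.0]))
        free = fit_sar_lag(y, x[:, None], W, row_standardize=False)
        fixed = SpatialLagRegressor(weights=W, row_standardize=False,
                                    fix_rho=0.0).fit(x[:, None], y)
        assert free.log_lik_ >= fixed.log_lik_ - 1e-10

    def test_slope_sign_invariant_to_joint_sign_flip(self):
        rng = np.random.default_rng(3)
        raw = rook_lattice_weights(7)
        W = raw / raw.sum(axis=1)[:, None]
        x, y = simulate_lag(rng, W, rho=0.4, beta=np.array([0.0, 0.8]))
        f1 = fit_sar_lag(y, x[:, None], W, row_standardize=False)
        f2 = fit_sar_lag(-y, -x[:, None], W, row_standardize=False)
        assert np.sign(f1.coef_[0]) == np.sign(f2.coef_[0])
        assert f1.coef_[0] == pytest.approx(f2.coef_[0], rel=1e-6)

    def test_standardized_ols_special_case_equals_pearson_r(self):
        rng = np.random.default_rng(4)
        raw = rook_lattice_weights(6)
        x = rng.standard_normal(36)
        y = 0.6 * x + rng.standard_normal(36)
        zx = (x - x.mean()) / x.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        fit = SpatialLagRegressor(weights=raw, fix_rho=0.0).fit(zx[:, None], zy)
        r = np.corrcoef(x, y)[0, 1]
        assert abs(fit.coef_[0]) == pytest.approx(abs(r), rel=1e-8)

    def test_rho_interval_and_convergence_flag(self):
        rng = np.random.default_rng(5)
        raw = rook_lattice_weights(8)
        W = raw / raw.sum(axis=1)[:, None]
        x, y = simulate_lag(rng, W, rho=0.5, beta=np.array([1.0, 0.5]))
        fit = fit_sar_lag(y, x[:, None], W, row_standardize=False)
        lo, hi = fit.rho_interval_
        assert lo < fit.rho_ < hi
        assert hi == pytest.approx(1.0, abs=1e-9)  # row-standardized
        assert fit.converged_
        assert fit.sigma2_ > 0 and np.isfinite(fit.log_lik_)


class TestWeightsHandling:
    def test_symmetric_kernel_standardized_internally(self):
        rng = np.random.default_rng(6)
        cells = pd.DataFrame({"lat_deg": rng.uniform(-5, 5, 40),
                              "lon_deg": rng.uniform(-72, -68, 40)})
        sw = build_weights(cells, KernelSpec("bisquare", 800.0),
                           include_self=False, row_standardize=False)
        x = rng.standard_normal(40)
        y = x + rng.standard_normal(40)
        fit = fit_sar_lag(y, x[:, None], sw)  # standardizes internally
        assert fit.rho_interval_[1] == pytest.approx(1.0, abs=1e-8)

    def test_prestandardized_spatialweights_accepted(self):
        rng = np.random.default_rng(7)
        cells = pd.DataFrame({"lat_deg": rng.uniform(-5, 5, 30),
                              "lon_deg": rng.uniform(-72, -68, 30)})
        sw = build_weights(cells, KernelSpec("bisquare", 900.0),
                           include_self=False, row_standardize=True)
        x = rng.standard_normal(30)
        y = x + rng.standard_normal(30)
        fit = fit_sar_lag(y, x[:, None], sw)
        assert np.isfinite(fit.log_lik_)

    def test_nonzero_diagonal_rejected(self):
        w = np.eye(20)
        with pytest.raises(ValueError, match="diagonal"):
            fit_sar_lag(np.random.default_rng(0).normal(size=20),
                        np.random.default_rng(1).normal(size=(20, 1)), w)

    def test_reduced_form_prediction_shape(self):
        rng = np.random.default_rng(8)
        raw = rook_lattice_weights(6)
        W = raw / raw.sum(axis=1)[:, None]
        x, y = simulate_lag(rng, W, rho=0.5, beta=np.array([1.0, 0.5]))
        fit = fit_sar_lag(y, x[:, None], W, row_standardize=False)
        pred = fit.predict(x[:, None])
        assert pred.shape == y.shape
        assert np.corrcoef(pred, y)[0, 1] > 0.3
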