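"""Maximum-likelihood spatial-lag (lagged SAR) regression.

The model is

    y = rho W y + X beta + eps,   eps ~ N(0, sigma^2 I),

with W a spatial weight matrix (here built from the same kernel as the GWR
whose local results are being analyzed — the lag term absorbs the *inherent*
autocorrelation that overlapping local regressions induce).

Estimation profiles the likelihood over rho:

    beta(rho)   = (X'X)^{-1} X' (I - rho W) y
    sigma2(rho) = e(rho)' e(rho) / n
    l(rho)      = -(n/2)(ln 2pi + ln sigma2(rho) + 1) + ln|I - rho W|

The log-determinant uses the precomputed eigenvalues of W:
ln|I - rho W| = sum_i ln(1 - rho lambda_i), and rho is searched by bounded
scalar optimization inside the admissible interval (1/lambda_min,
1/lambda_max).  With row-standardized weights lambda_max = 1.

Standard errors for beta are conditional on the estimated rho
(sigma2_hat (X'X)^{-1}), the common first-order approximation; inference on
beta is by two-sided z-tests.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .spatial_weights import SpatialWeights

_BOUNDARY_TOL = 1e-6


def _lag_eigenvalues(W: np.ndarray, assume_similar_symmetric: bool) -> np.ndarray:
    """Real eigenvalues of the weight matrix.

    A matrix that is symmetric, or row-standardized from a symmetric kernel
    (similar to a symmetric matrix), has a real spectrum; residual imaginary
    parts beyond tolerance are an error.
    """
    if np.allclose(W, W.T, atol=1e-12):
        return np.linalg.eigvalsh(W)
    lam = np.linalg.eigvals(W)
    tol = 1e-8 * max(1.0, np.abs(lam).max())
    if np.abs(lam.imag).max() > tol and not assume_similar_symmetric:
        raise ValueError("weight matrix has genuinely complex eigenvalues")
    return np.sort(lam.real)


class SpatialLagRegressor(RegressorMixin, BaseEstimator):
    """Lagged SAR model estimated by profile maximum likelihood.

    Parameters
    ----------
    weights : SpatialWeights or (n, n) ndarray
        Spatial weight structure with zero diagonal.  A symmetric kernel
        matrix is row-standardized internally when ``row_standardize`` is
        true (the default, which bounds the admissible rho interval at 1);
        set it to false to fit with the raw symmetric kernel.
    row_standardize : bool

    The weight matrix is tied to the observation set, so ``fit(X, y)`` must
    receive exactly the n rows the weights were built for.

    Attributes (after fit)
    ----------
    rho_ : spatial-lag coefficient
    coef_, intercept_ : regression coefficients
    se_, z_values_, p_values_ : inference on (intercept, slopes)
    sigma2_, log_lik_, rho_interval_, converged_
    """

    def __init__(self, weights=None, row_standardize: bool = True,
                 fix_rho: float | None = None):
        self.weights = weights
        self.row_standardize = row_standardize
        self.fix_rho = fix_rho  # hold rho fixed (e.g. 0 for the OLS special case)

    def _resolve_weights(self, n: int):
        w = self.weights
        if w is None:
            raise ValueError("SpatialLagRegressor requires a weights matrix")
        already_standardized = False
        if isinstance(w, SpatialWeights):
            already_standardized = w.row_standardized
            w = w.matrix
        W = np.asarray(w, float)
        if W.shape != (n, n):
            raise ValueError(f"weights are {W.shape}, data have n = {n}")
        if np.any(np.diag(W) != 0):
            raise ValueError("weight matrix must have a zero diagonal")

        similar_symmetric = False
        if self.row_standardize and not already_standardized:
            rowsum = W.sum(axis=1)
            if np.any(rowsum == 0):
                raise ValueError("isolated observation: a row of weights sums to 0")
            if np.allclose(W, W.T, atol=1e-12):
                # eigenvalues via the similar symmetric form D^-1/2 K D^-1/2
                dinv = 1.0 / np.sqrt(rowsum)
                lam = np.linalg.eigvalsh(W * np.outer(dinv, dinv))
                W = W / rowsum[:, None]
                return W, lam
            W = W / rowsum[:, None]
            similar_symmetric = True
        return W, _lag_eigenvalues(W, already_standardized or similar_symmetric)

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        n, p = X.shape
        if n <= p + 2:
            raise ValueError("need n > p + 2 observations")
        W, lam = self._resolve_weights(n)

        lam_min, lam_max = lam.min(), lam.max()
        if lam_min >= 0 or lam_max <= 0:
            raise ValueError("degenerate weight spectrum; cannot bound rho")
        lo, hi = 1.0 / lam_min, 1.0 / lam_max
        self.rho_interval_ = (float(lo), float(hi))

        Xd = np.column_stack([np.ones(n), X])
        XtX = Xd.T @ Xd
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            raise ValueError("singular X'X in SAR fit") from None
        H = XtX_inv @ Xd.T
        Wy = W @ y
        e0 = y - Xd @ (H @ y)    # residuals of y on X
        ed = Wy - Xd @ (H @ Wy)  # residuals of Wy on X

        def neg_profile_loglik(rho):
            e = e0 - rho * ed
            sigma2 = (e @ e) / n
            logdet = np.sum(np.log1p(-rho * lam))
            return 0.5 * n * (np.log(2 * np.pi) + np.log(sigma2) + 1.0) - logdet

        if self.fix_rho is not None:
            if not lo < self.fix_rho < hi:
                raise ValueError(f"fix_rho outside admissible interval ({lo}, {hi})")
            rho = float(self.fix_rho)
            self.rho_ = rho
            self.converged_ = True
        else:
            eps = 1e-9 * (hi - lo)
            res = optimize.minimize_scalar(
                neg_profile_loglik, bounds=(lo + eps, hi - eps), method="bounded",
                options={"xatol": 1e-8},
            )
            rho = float(res.x)
            self.rho_ = rho
            self.converged_ = bool(
                res.success
                and (rho - lo) > _BOUNDARY_TOL * (hi - lo)
                and (hi - rho) > _BOUNDARY_TOL * (hi - lo)
            )

        beta = H @ (y - rho * Wy)
        e = (y - rho * Wy) - Xd @ beta
        sigma2 = float(e @ e) / n
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.params_ = beta
        self.sigma2_ = sigma2
        self.log_lik_ = float(-neg_profile_loglik(rho))
        self.se_ = np.sqrt(sigma2 * np.diag(XtX_inv))
        with np.errstate(divide="ignore", invalid="ignore"):
            self.z_values_ = beta / self.se_
        self.p_values_ = 2.0 * stats.norm.sf(np.abs(self.z_values_))
        self._W = W
        self.n_features_in_ = p
        return self

    def predict(self, X):
        """Reduced-form mean (I - rho W)^{-1} X beta at the fitted locations."""
        check_is_fitted(self, "rho_")
        X = check_array(X)
        n = self._W.shape[0]
        if X.shape[0] != n:
            raise ValueError("predict requires the n rows the weights were built for")
        xb = self.intercept_ + X @ self.coef_
        return np.linalg.solve(np.eye(n) - self.rho_ * self._W, xb)

    def summary_dict(self) -> dict:
        check_is_fitted(self, "rho_")
        return {
            "rho": self.rho_,
            "beta": self.params_.tolist(),
            "se": self.se_.tolist(),
            "z": self.z_values_.tolist(),
            "p": self.p_values_.tolist(),
            "sigma2": self.sigma2_,
            "logLik": self.log_lik_,
            "rho_interval": list(self.rho_interval_),
            "converged": self.converged_,
        }


def fit_sar_lag(y, X, weights, row_standardize: bool = True) -> SpatialLagRegressor:
    """Fit a lagged SAR of ``y`` on ``X`` (no intercept column) with the
    given spatial weights; returns the fitted estimator."""
    est = SpatialLagRegressor(weights=weights, row_standardize=row_standardize)
    return est.fit(np.asarray(X, float), np.asarray(y, float))


def log_det_from_eigenvalues(rho: float, lam: np.ndarray) -> float:
    """ln|I - rho W| from the eigenvalues of W (used by tests as a seam)."""
    return float(np.sum(np.log1p(-rho * np.asarray(lam, float))))
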