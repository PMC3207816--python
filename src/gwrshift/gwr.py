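"""Geographically weighted regression (GWR) and matched global OLS.

GWR fits one weighted least-squares regression per observation, weighting
the other observations by a distance kernel centered on the focal cell.  The
result is a spatially varying coefficient vector and a *local* coefficient of
determination per cell, plus an effective number of parameters tr(S) (the
trace of the hat matrix of the whole GWR predictor) that enters the
small-sample corrected AIC

    AICc = 2 n ln(sigma_hat) + n ln(2 pi) + n (n + tr(S)) / (n - 2 - tr(S)),

with sigma_hat^2 = RSS / n.  The same formula with tr(S) replaced by p + 1
scores a global OLS fit, so GWR and OLS AICc values are directly comparable.

`GWRegressor` is a scikit-learn style estimator; the module-level functions
(`fit_gwr`, `aicc_ols`, `select_model`, ...) are thin wrappers operating on
cell tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .cell_data import VariableSet
from .spatial_weights import KernelSpec, distance_matrix_km, kernel_weight


def gwr_aicc(n: int, rss: float, trace_s: float) -> float:
    """Small-sample corrected AIC for a linear smoother with tr(S) effective
    parameters; undefined (raises) when tr(S) >= n - 2."""
    if trace_s >= n - 2:
        raise ValueError(
            f"tr(S) = {trace_s:.2f} >= n - 2 = {n - 2}; AICc undefined "
            "(bandwidth too small for this grid)"
        )
    sigma2 = rss / n
    return float(
        n * np.log(sigma2) + n * np.log(2 * np.pi)
        + n * (n + trace_s) / (n - 2 - trace_s)
    )


def local_wls(X: np.ndarray, y: np.ndarray, w: np.ndarray,
              max_condition: float = 1e10):
    """One focal-cell weighted least-squares fit.

    ``X`` must already carry an intercept column.  Returns
    ``(beta, local_r2, hat_gram_inv, reliable)`` where ``hat_gram_inv`` is
    (X^T W X)^(-1) restricted to the fitted columns (None when unreliable).
    A fit is unreliable — coefficients withheld as NaN — when fewer than
    p + 2 observations have positive weight, or the weighted design is rank
    deficient / has condition number beyond ``max_condition``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    p1 = X.shape[1]
    mask = w > 0
    nobs = int(mask.sum())
    if nobs < p1 + 1:  # p predictors + intercept = p1 columns; need p+2 points
        return np.full(p1, np.nan), np.nan, None, False

    ws = w[mask]
    Xm = X[mask]
    ym = y[mask]
    sw = np.sqrt(ws)
    A = Xm * sw[:, None]
    b = ym * sw

    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    if s[0] <= 0 or s[-1] <= s[0] * 1e-10 or (s[0] / s[-1]) > max_condition:
        return np.full(p1, np.nan), np.nan, None, False
    beta = Vt.T @ ((U.T @ b) / s)

    fitted = Xm @ beta
    ybar_w = np.average(ym, weights=ws)
    tss = np.sum(ws * (ym - ybar_w) ** 2)
    rss = np.sum(ws * (ym - fitted) ** 2)
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    # (X^T W X)^{-1} = V diag(s^-2) V^T, reused for the hat-matrix trace
    gram_inv = (Vt.T / s**2) @ Vt
    return beta, float(r2), gram_inv, True


class GWRegressor(RegressorMixin, BaseEstimator):
    """Geographically weighted regression with a fixed spatial kernel.

    Parameters
    ----------
    kernel : {"bisquare", "moving_window"}
        Distance-weighting family.
    bandwidth_km : float
        Kernel bandwidth b in km (weights vanish at/beyond b).
    max_condition : float
        Condition-number ceiling above which a local fit is flagged
        unreliable and its coefficients withheld.

    The focal cell participates in its own local regression with weight 1.

    Attributes (after ``fit(X, y, coords=...)``)
    ----------
    coef_ : (n_cells, n_features) local slopes (NaN where unreliable)
    intercept_ : (n_cells,) local intercepts
    local_r2_ : (n_cells,) weighted local coefficient of determination
    reliable_ : (n_cells,) bool flags
    fitted_values_, residuals_ : focal-cell predictions y_i - x_i' beta_i
    trace_S_ : effective number of parameters (hat-matrix trace)
    aicc_ : corrected AIC of the whole GWR fit
    """

    def __init__(self, kernel: str = "bisquare", bandwidth_km: float = 1200.0,
                 max_condition: float = 1e10):
        self.kernel = kernel
        self.bandwidth_km = bandwidth_km
        self.max_condition = max_condition

    def fit(self, X, y, coords=None):
        """Fit local regressions at every observation.

        ``coords`` is an (n, 2) array of (lat_deg, lon_deg) cell centers;
        it is required (GWR is meaningless without locations).
        """
        X, y = check_X_y(X, y, y_numeric=True)
        if coords is None:
            raise ValueError("GWRegressor.fit requires coords=(lat_deg, lon_deg)")
        coords = check_array(coords)
        if coords.shape != (X.shape[0], 2):
            raise ValueError("coords must be (n_samples, 2) lat/lon degrees")

        spec = KernelSpec(self.kernel, self.bandwidth_km)
        n, p = X.shape
        Xd = np.column_stack([np.ones(n), X])
        dmat = distance_matrix_km(coords[:, 0], coords[:, 1])
        W = kernel_weight(dmat, spec)

        coef = np.full((n, p), np.nan)
        intercept = np.full(n, np.nan)
        local_r2 = np.full(n, np.nan)
        reliable = np.zeros(n, bool)
        fitted = np.full(n, np.nan)
        s_ii = np.full(n, np.nan)

        for i in range(n):
            beta, r2, gram_inv, ok = local_wls(Xd, y, W[i], self.max_condition)
            reliable[i] = ok
            if not ok:
                continue
            intercept[i] = beta[0]
            coef[i] = beta[1:]
            local_r2[i] = r2
            fitted[i] = Xd[i] @ beta
            # hat-matrix diagonal: s_ii = w_ii x_i' (X'WX)^{-1} x_i
            s_ii[i] = W[i, i] * Xd[i] @ gram_inv @ Xd[i]

        if not reliable.any():
            raise ValueError("no reliable local fits; bandwidth too small")

        self.kernel_spec_ = spec
        self.coords_ = coords
        self.n_features_in_ = p
        self.coef_ = coef
        self.intercept_ = intercept
        self.local_r2_ = local_r2
        self.reliable_ = reliable
        self.fitted_values_ = fitted
        self.residuals_ = y - fitted
        self.hat_diag_ = s_ii
        self.trace_S_ = float(np.nansum(s_ii))

        ok = reliable
        rss = float(np.sum(self.residuals_[ok] ** 2))
        self.rss_ = rss
        self.aicc_ = gwr_aicc(int(ok.sum()), rss, self.trace_S_)
        return self

    def predict(self, X, coords=None):
        """Predict with the local coefficients of the nearest fitted cell.

        At the training locations this returns the focal fitted values.
        """
        check_is_fitted(self, "coef_")
        X = check_array(X)
        if coords is None:
            raise ValueError("predict requires coords=(lat_deg, lon_deg)")
        coords = check_array(coords)
        from .spatial_weights import great_circle_km

        d = great_circle_km(
            coords[:, 0][:, None], coords[:, 1][:, None],
            self.coords_[:, 0][None, :], self.coords_[:, 1][None, :],
        )
        d = np.where(self.reliable_[None, :], d, np.inf)
        nearest = np.argmin(d, axis=1)
        return (self.intercept_[nearest]
                + np.sum(X * self.coef_[nearest], axis=1))


@dataclass
class GWRFit:
    """A fitted GWR over a cell table: estimator plus bookkeeping."""

    estimator: GWRegressor
    predictors: VariableSet
    kernel: KernelSpec
    cell_ids: np.ndarray
    lat_deg: np.ndarray
    lon_deg: np.ndarray

    @property
    def local_r2(self) -> np.ndarray:
        return self.estimator.local_r2_

    @property
    def reliable(self) -> np.ndarray:
        return self.estimator.reliable_

    @property
    def aicc(self) -> float:
        return self.estimator.aicc_

    @property
    def trace_S(self) -> float:
        return self.estimator.trace_S_

    def locals_frame(self) -> pd.DataFrame:
        """Per-cell local results table (coefficients, local R^2, flag)."""
        est = self.estimator
        out = pd.DataFrame({
            "cell_id": self.cell_ids,
            "lat_deg": self.lat_deg,
            "lon_deg": self.lon_deg,
            "intercept": est.intercept_,
        })
        for k, name in enumerate(self.predictors.members):
            out[f"b_{name}"] = est.coef_[:, k]
        out["local_R2"] = est.local_r2_
        out["reliable"] = est.reliable_
        return out


def fit_gwr(table: pd.DataFrame, predictors: VariableSet | list[str],
            kernel: KernelSpec, response: str = "richness") -> GWRFit:
    """Fit a GWR of ``response`` on the given predictor columns of a cell table."""
    if not isinstance(predictors, VariableSet):
        predictors = VariableSet("combined", tuple(predictors))
    if not predictors.members:
        raise ValueError("empty predictor set")
    X = table[list(predictors.members)].to_numpy(float)
    y = table[response].to_numpy(float)
    coords = table[["lat_deg", "lon_deg"]].to_numpy(float)
    est = GWRegressor(kernel.family, kernel.bandwidth_km).fit(X, y, coords=coords)
    return GWRFit(
        estimator=est, predictors=predictors, kernel=kernel,
        cell_ids=table["cell_id"].to_numpy(),
        lat_deg=coords[:, 0], lon_deg=coords[:, 1],
    )


def aicc_ols(table: pd.DataFrame, predictors, response: str = "richness"):
    """Global OLS with the identical AICc formula (tr(S) -> p + 1).

    Returns ``(coefficients, aicc)`` with the intercept first, enabling a
    like-for-like Delta AICc against `fit_gwr` on the same cells.
    """
    members = predictors.members if isinstance(predictors, VariableSet) else tuple(predictors)
    X = table[list(members)].to_numpy(float)
    y = table[response].to_numpy(float)
    n = len(y)
    Xd = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
    if rank < Xd.shape[1]:
        raise ValueError("rank-deficient design in global OLS")
    resid = y - Xd @ beta
    rss = float(resid @ resid)
    return beta, gwr_aicc(n, rss, Xd.shape[1])


def select_model(table: pd.DataFrame, variable_set: VariableSet,
                 kernel: KernelSpec) -> pd.DataFrame:
    """All-subsets GWR model selection within one 3-variable set.

    Fits the 7 non-empty subsets (3 singletons, 3 pairs, 1 triple) and ranks
    them by AICc.  Returns a table with columns ``subset`` (tuple of
    predictor names), ``aicc``, ``delta_aicc`` and ``best``.
    """
    members = variable_set.members
    if len(members) != 3:
        raise ValueError("all-subsets selection expects a 3-variable set")
    rows = []
    for k in (1, 2, 3):
        for subset in itertools.combinations(members, k):
            fit = fit_gwr(table, VariableSet(variable_set.name, subset), kernel)
            rows.append({"subset": subset, "aicc": fit.aicc})
    out = pd.DataFrame(rows).sort_values("aicc", kind="stable").reset_index(drop=True)
    out["delta_aicc"] = out["aicc"] - out["aicc"].iloc[0]
    out["best"] = out["delta_aicc"] == 0.0
    if out["best"].sum() != 1:  # exact AICc ties are a degenerate input
        out["best"] = False
        out.loc[0, "best"] = True
    return out


def best_subset(selection: pd.DataFrame, name: str) -> VariableSet:
    """Extract the minimum-AICc subset from a `select_model` table."""
    subset = selection.loc[selection["best"], "subset"].iloc[0]
    return VariableSet(name, tuple(subset))


def combined_model(best_water: VariableSet, best_energy: VariableSet) -> VariableSet:
    """Union of the best water and best energy subsets (water members first)."""
    members = tuple(dict.fromkeys(tuple(best_water.members) + tuple(best_energy.members)))
    if not members:
        raise ValueError("combined model would be empty")
    return VariableSet("combined", members)
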