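import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import gwrshift as g
from gwrshift.cell_data import ENERGY_SET, WATER_SET, VariableSet
from gwrshift.gwr import (GWRegressor, aicc_ols, best_subset, combined_model,
                          fit_gwr, gwr_aicc, local_wls, select_model)
from gwrshift.spatial_weights import KernelSpec, distance_matrix_km, kernel_weight


def brute_force_wls(X, y, w):
    """Independent oracle: weighted normal equations by explicit inversion."""
    W = np.diag(w)
    beta = np.linalg.inv(X.T @ W @ X) @ X.T @ W @ y
    ybar = np.sum(w * y) / np.sum(w)
    rss = np.sum(w * (y - X @ beta) ** 2)
    tss = np.sum(w * (y - ybar) ** 2)
    return beta, 1 - rss / tss


class TestLocalWLS:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 3))])
        y = rng.normal(size=30)
        w = rng.uniform(0.1, 1.0, 30)
        beta, r2, _, ok = local_wls(X, y, w)
        beta_o, r2_o = brute_force_wls(X, y, w)
        assert ok
        assert np.allclose(beta, beta_o, rtol=1e-8)
        assert r2 == pytest.approx(r2_o, rel=1e-8)

    def test_uniform_weights_equal_ols(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(25), rng.normal(size=(25, 2))])
        y = rng.normal(size=25)
        beta, _, _, _ = local_wls(X, y, np.ones(25))
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(beta, beta_ols, rtol=1e-10)

    def test_exact_linear_response_gives_r2_one(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        y = X @ np.array([1.0, 2.0, -0.5])
        beta, r2, _, ok = local_wls(X, y, np.full(20, 0.7))
        assert ok and r2 == pytest.approx(1.0, abs=1e-10)

    def test_too_few_positive_weights_is_unreliable_not_fatal(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = np.arange(10.0)
        w = np.zeros(10)
        w[:2] = 1.0  # < p + 2 = 3 positive weights
        beta, r2, _, ok = local_wls(X, y, w)
        assert not ok and np.all(np.isnan(beta)) and np.isnan(r2)

    def test_collinear_design_flagged_unreliable(self):
        x = np.arange(12.0)
        X = np.column_stack([np.ones(12), x, 2 * x])
        _, _, _, ok = local_wls(X, x, np.ones(12))
        assert not ok


class TestGWRFitting:
    def test_degenerate_bandwidth_reproduces_global_ols(self, shift_table):
        kernel = KernelSpec("moving_window", 1e9)
        fit = fit_gwr(shift_table, WATER_SET, kernel)
        beta_ols, aicc = aicc_ols(shift_table, WATER_SET)
        est = fit.estimator
        for i in range(0, len(shift_table), 37):
            local = np.concatenate([[est.intercept_[i]], est.coef_[i]])
            assert np.allclose(local, beta_ols, atol=1e-10)
        assert est.trace_S_ == pytest.approx(len(WATER_SET.members) + 1, abs=1e-8)
        assert est.aicc_ == pytest.approx(aicc, abs=1e-8)

    def test_trace_matches_dense_hat_matrix_oracle(self):
        rng = np.random.default_rng(5)
        n = 40
        tab = pd.DataFrame({
            "cell_id": np.arange(n), "lat_deg": rng.uniform(-10, 10, n),
            "lon_deg": rng.uniform(-75, -65, n),
            "richness": rng.integers(0, 100, n).astype(float),
            "AP": rng.normal(2000, 300, n), "MPDM": rng.normal(90, 20, n),
        })
        kernel = KernelSpec("bisquare", 1500.0)
        fit = fit_gwr(tab, VariableSet("water", ("AP", "MPDM")), kernel)
        # independent dense assembly of every hat-matrix row
        Xd = np.column_stack([np.ones(n), tab[["AP", "MPDM"]].to_numpy()])
        d = distance_matrix_km(tab.lat_deg.to_numpy(), tab.lon_deg.to_numpy())
        trace = 0.0
        for i in range(n):
            Wi = np.diag(kernel_weight(d[i], kernel))
            Si = Xd[i] @ np.linalg.inv(Xd.T @ Wi @ Xd) @ Xd.T @ Wi
            trace += Si[i]
        assert fit.trace_S == pytest.approx(trace, abs=1e-10)

    def test_aicc_hand_computed_small_ols(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=10)
        y = 2 + 0.5 * x + rng.normal(size=10)
        tab = pd.DataFrame({"cell_id": range(10), "lat_deg": 0.0, "lon_deg": 0.0,
                            "richness": y, "AP": x})
        _, aicc = aicc_ols(tab, VariableSet("water", ("AP",)))
        X = np.column_stack([np.ones(10), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = np.sum((y - X @ beta) ** 2)
        n, k = 10, 2
        expected = (2 * n * np.log(np.sqrt(rss / n)) + n * np.log(2 * np.pi)
                    + n * (n + k) / (n - 2 - k))
        assert aicc == pytest.approx(expected, abs=1e-9)

    def test_aicc_invariant_to_affine_predictor_rescaling(self, shift_table):
        kernel = KernelSpec("bisquare", 1200.0)
        a = fit_gwr(shift_table, WATER_SET, kernel).aicc
        scaled = shift_table.copy()
        scaled["AP"] = scaled["AP"] / 1000.0 + 3.0
        scaled["WD"] = scaled["WD"] * 25.4
        b = fit_gwr(scaled, WATER_SET, kernel).aicc
        assert a == pytest.approx(b, rel=1e-9)

    def test_local_r2_monotone_under_nesting(self, shift_fits):
        fw, fc = shift_fits["water"], shift_fits["combined"]
        ok = fw.reliable & fc.reliable
        assert np.all(fc.local_r2[ok] >= fw.local_r2[ok] - 1e-12)

    def test_gwr_beats_ols_under_nonstationarity(self, shift_fits, shift_table):
        _, ols = aicc_ols(shift_table, shift_fits["combined"].predictors)
        assert ols - shift_fits["combined"].aicc > 0

    def test_coefficient_spread_shrinks_with_bandwidth(self, shift_table):
        f12 = fit_gwr(shift_table, WATER_SET, KernelSpec("bisquare", 1200.0))
        f18 = fit_gwr(shift_table, WATER_SET, KernelSpec("bisquare", 1800.0))
        spread12 = np.nanstd(f12.estimator.coef_, axis=0)
        spread18 = np.nanstd(f18.estimator.coef_, axis=0)
        assert np.all(spread18 <= spread12)

    def test_aicc_undefined_when_overfit(self):
        with pytest.raises(ValueError, match="AICc undefined"):
            gwr_aicc(10, 1.0, 9.0)


class TestModelSelection:
    def test_seven_subsets_ranked_with_zero_delta_best(self, shift_table):
        sel = select_model(shift_table, WATER_SET, KernelSpec("bisquare", 1200.0))
        assert len(sel) == 7
        sizes = sorted(sel["subset"].map(len))
        assert sizes == [1, 1, 1, 2, 2, 2, 3]
        assert sel["delta_aicc"].iloc[0] == 0.0
        assert sel["best"].sum() == 1
        assert (sel["delta_aicc"] >= 0).all()

    def test_single_driver_is_selected(self):
        # richness built from AP alone: the best subset must contain AP
        rng = np.random.default_rng(11)
        hits = 0
        for seed in range(5):
            cfg = g.scenario("stationary", seed=seed,
                             lat_range=(-8.0, 9.0), lon_range=(-75.0, -67.0))
            tab = g.filter_cells(g.derive_water_deficit(g.generate_cells(cfg)))
            tab = tab.copy()
            ap = (tab["AP"] - tab["AP"].mean()) / tab["AP"].std()
            tab["richness"] = np.round(np.maximum(
                0, 50 + 20 * ap + rng.normal(0, 5, len(tab)))).astype(int)
            sel = select_model(tab, WATER_SET, KernelSpec("bisquare", 1200.0))
            if "AP" in sel["subset"].iloc[0]:
                hits += 1
        assert hits >= 4

    def test_combined_model_union_order_and_dedup(self):
        bw = VariableSet("water", ("AP", "WD"))
        be = VariableSet("energy", ("MAT", "PET"))
        combo = combined_model(bw, be)
        assert combo.members == ("AP", "WD", "MAT", "PET")
        full = combined_model(WATER_SET, ENERGY_SET)
        assert len(full.members) == 6

    def test_best_subset_extraction(self, shift_table):
        sel = select_model(shift_table, ENERGY_SET, KernelSpec("bisquare", 1200.0))
        best = best_subset(sel, "energy")
        assert set(best.members) <= set(ENERGY_SET.members)


class TestEstimatorAPI:
    def test_sklearn_params_and_clone(self):
        est = GWRegressor(kernel="moving_window", bandwidth_km=1800.0)
        params = est.get_params()
        assert params["bandwidth_km"] == 1800.0
        est2 = clone(est).set_params(bandwidth_km=1200.0)
        assert est2.get_params()["bandwidth_km"] == 1200.0

    def test_fit_requires_coords(self):
        with pytest.raises(ValueError, match="coords"):
            GWRegressor().fit(np.random.default_rng(0).normal(size=(20, 2)),
                              np.zeros(20))

    def test_predict_at_training_locations(self, shift_table, shift_fits):
        est = shift_fits["water"].estimator
        X = shift_table[list(WATER_SET.members)].to_numpy()
        coords = shift_table[["lat_deg", "lon_deg"]].to_numpy()
        pred = est.predict(X, coords=coords)
        assert np.allclose(pred, est.fitted_values_, atol=1e-9)
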