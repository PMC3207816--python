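# gwrshift

**Latitudinal shifts in the explanatory power of water vs. energy on gridded
species richness.**

Water availability and ambient energy are the two leading contemporary
correlates of broad-scale species richness. Water–energy dynamics theory
predicts their *relative* importance shifts with latitude: water limits
richness where energy is plentiful (low latitudes), energy limits richness
where it is scarce (high latitudes). `gwrshift` implements a local-modeling
pipeline for testing this prediction on a 1°×1° richness grid — e.g. a
megathermal plant group such as the American palms — together with a seeded
synthetic-data generator that emulates such a dataset with *known*,
latitude-varying climate–richness coefficients, so every step of the
pipeline can be validated against ground truth.

## The method

1. **Geographically weighted regression (GWR).** One weighted least-squares
   fit per grid cell, with weights from a fixed spatial kernel — bi-square
   `w(d) = (1 − (d/b)²)²` for `d < b`, or a moving window (indicator) — at
   bandwidths `b` = 1200 and 1800 km. Each cell gets local coefficients and
   a local R². The whole fit is scored by the small-sample corrected AIC,
   `AICc = 2n ln σ̂ + n ln 2π + n(n + tr(S))/(n − 2 − tr(S))`, with `tr(S)`
   the hat-matrix trace (effective number of parameters); a global OLS fit
   is scored with the identical formula (`tr(S) → p + 1`) so
   ΔAICc(OLS − GWR) measures spatial non-stationarity.
2. **All-subsets model selection** by AICc within a *water* set (annual
   precipitation AP, driest-month precipitation MPDM, water deficit
   WD = PET − AET) and an *energy* set (mean annual temperature MAT,
   coldest-month minimum MTCM, potential evapotranspiration PET).
3. **Per-cell variation partitioning** of local explained variance: with
   `R_w`, `R_e`, `R_t` the local R² of the best water, best energy and
   combined models, pure water is `R_pw = R_t − R_e`, pure energy is
   `R_pe = R_t − R_w`, and `shared = R_w + R_e − R_t`.
4. **Moran's I correlograms** of the local-R² surfaces in great-circle
   distance bands, quantifying the inherent spatial autocorrelation that
   overlapping local regressions induce.
5. **Latitudinal trend tests.** Each response (`R_w`, `R_e`, `R_pw`,
   `R_pe`), z-scored within a hemisphere, is regressed on z-scored absolute
   latitude with (a) OLS and (b) a maximum-likelihood spatial-lag model
   `y = ρWy + Xβ + ε` whose weights reuse the GWR kernel — because the
   inherent autocorrelation of GWR outputs makes naive OLS trend tests
   anticonservative. The shift hypothesis predicts slope(R_pw) < 0 and
   slope(R_pe) > 0.

GWR and the spatial-lag model are scikit-learn-style estimators
(`GWRegressor`, `SpatialLagRegressor`); the pipeline functions wrap them.

## Worked example

```python
import gwrshift as g

# simulate a palm-like grid where water loses and energy gains
# explanatory power away from the equator
table = g.generate_dataset(g.scenario("predictor_shift", seed=1))
table = g.filter_cells(g.derive_water_deficit(table))

kernel = g.KernelSpec("bisquare", 1200.0)
fit_w = g.fit_gwr(table, g.WATER_SET, kernel)
fit_e = g.fit_gwr(table, g.ENERGY_SET, kernel)
fit_c = g.fit_gwr(table, g.combined_model(g.WATER_SET, g.ENERGY_SET), kernel)
_, ols_aicc = g.aicc_ols(table, fit_c.predictors)
print(f"AICc(GWR combined) = {fit_c.aicc:.1f}  AICc(OLS) = {ols_aicc:.1f}")

part = g.partition_local(fit_w, fit_e, fit_c)
for resp, label in [("R_pw", "pure water"), ("R_pe", "pure energy")]:
    for method in ("ols", "sar"):
        r = g.fit_latitudinal_trend(part, resp, "north", method, kernel)
        print(f"{label:12s} {method.upper():3s} slope vs |lat| (north): "
              f"{r.slope:+.3f}  p = {r.p_value:.2e}")
```

Output:

```
AICc(GWR combined) = 11249.1  AICc(OLS) = 11789.2
pure water   OLS slope vs |lat| (north): -0.937  p = 0.00e+00
pure water   SAR slope vs |lat| (north): -0.063  p = 1.04e-18
pure energy  OLS slope vs |lat| (north): +0.804  p = 2.86e-186
pure energy  SAR slope vs |lat| (north): +0.042  p = 4.71e-04
```

Reading this: the GWR fits the 1608-cell grid far better than a single
global regression (ΔAICc ≈ 540 — strong spatial non-stationarity). The
unique contribution of water to locally explained richness variance falls
with absolute latitude while that of energy rises — the predictor-shift
signature. The spatial-lag slopes are strongly attenuated relative to OLS
(the smooth local-R² surfaces carry few independent observations) but remain
significant with the same signs.

The same analysis is available from the shell, stage by stage or end to end:

```bash
gwrshift simulate --scenario predictor_shift --seed 1 --out cells.csv
gwrshift prepare  --input cells.csv --out prepared.csv
gwrshift all      --scenario predictor_shift --seed 1 --outdir run1/
```

## Layout

- `src/gwrshift/cell_data.py` — cell-table schema, filters, derived variables
- `src/gwrshift/spatial_weights.py` — haversine distances, kernels, weight matrices
- `src/gwrshift/gwr.py` — `GWRegressor`, AICc, all-subsets selection
- `src/gwrshift/partition.py` — per-cell variation partitioning
- `src/gwrshift/autocorr.py` — Moran's I and distance-band correlograms
- `src/gwrshift/sar.py` — `SpatialLagRegressor` (profile-ML spatial lag)
- `src/gwrshift/trends.py` — latitudinal trend regressions, summary tables
- `src/gwrshift/synthetics.py` — seeded palm-like grid generator
- `src/gwrshift/pipeline.py`, `cli.py` — orchestration and the `gwrshift` command

See `docs/methods.md` for the modeling choices, generator design and known
limitations.
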