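# Methods

This note documents the statistical models implemented in `gwrshift`, the
conventions adopted where the methods literature offers more than one, the
design of the synthetic-data generator, and the known limitations of both.

## Data model

The unit of analysis is a 1°×1° grid cell with center coordinates, a land
fraction, a species richness count, and six climate variables: annual
precipitation AP (mm/yr), minimum precipitation of the driest month MPDM
(mm/month), mean annual temperature MAT (°C), minimum temperature of the
coldest month MTCM (°C), potential evapotranspiration PET (mm/yr) and actual
evapotranspiration AET (mm/yr). Water deficit WD = PET − AET (mm) is derived;
AET itself is never a predictor because it confounds water and energy. The
predictor sets are *water* = {AP, MPDM, WD} and *energy* = {MAT, MTCM, PET}.

Filtering: cells with land fraction strictly below 0.25 are dropped (a cell
at exactly 0.25 is retained), as are cells with any missing climate value.
Hemispheres are split at the cell-center latitude, with latitude exactly 0
assigned north — a convention that never triggers on 1° grids centered at
half degrees. Standardization always uses the sample (n − 1) standard
deviation.

## Geographically weighted regression

For focal cell *i* with kernel weights `w_i(d)` over all cells (the focal
cell included with weight 1), the local fit is weighted least squares
`β_i = (XᵀW_iX)⁻¹XᵀW_iy`. Conventions:

- **Kernels.** Bi-square `(1 − (d/b)²)²` for `d < b` (zero at and beyond the
  bandwidth), and the moving window, which *includes* its boundary
  (`d ≤ b`). Distances are haversine great-circle distances between cell
  centers on a sphere of radius 6371.0 km. Bandwidths are fixed (1200 and
  1800 km by default); adaptive bandwidths are deliberately out of scope so
  marginal areas respond on their own.
- **Local R²** is the weighted coefficient of determination around the
  weighted mean: `1 − Σw(y − ŷ)² / Σw(y − ȳ_w)²`.
- **Reliability.** A local fit needs at least p + 2 positive-weight
  observations and a weighted-design condition number ≤ 1e10; otherwise its
  coefficients and local R² are withheld as NA and the cell is excluded
  (with counts logged) from downstream responses. Local solves use an SVD,
  never explicit inversion, with singular values below 1e−10 of the largest
  treated as rank deficiency.
- **AICc.** The small-sample corrected AIC for linear smoothers,
  `AICc = 2n ln σ̂ + n ln 2π + n(n + tr S)/(n − 2 − tr S)` with
  `σ̂² = RSS/n` and `tr S = Σᵢ w_ii x_iᵀ(XᵀW_iX)⁻¹x_i` the hat-matrix trace.
  Global OLS is scored with the identical formula (`tr S = p + 1`), which
  makes ΔAICc(OLS − GWR) a like-for-like non-stationarity measure and makes
  GWR with an infinitely wide moving window *exactly* reproduce OLS,
  including its AICc — a property the test suite asserts. AICc is undefined
  (an error, signalling an overfitting bandwidth) when `tr S ≥ n − 2`.
- **Model selection.** Within each 3-variable set, all 7 non-empty subsets
  are fitted and ranked by AICc; the combined model is the ordered,
  de-duplicated union of the two winners (water members first).

## Variation partitioning

With `R_w`, `R_e`, `R_t` the local R² of the best water, best energy and
combined models (same cells, same kernel), `R_pw = R_t − R_e`,
`R_pe = R_t − R_w`, `shared = R_w + R_e − R_t`. Because the three fits are
nested least-squares problems sharing each cell's weights, `R_t ≥ max(R_w,
R_e)` holds algebraically; negatives beyond −1e−9 therefore indicate an
internal inconsistency and raise an error rather than being clamped (tiny
round-off negatives are clamped to 0, preserving the exact three-way
identity). The shared fraction is reported even though only the pure
fractions enter the headline test: it is free, and it quantifies the
water–energy collinearity that motivates partitioning in the first place.

## Moran's I correlograms

Classical Moran's I, `I = (n/S0)(zᵀWz)/(zᵀz)`, on half-open great-circle
distance bands `[lo, hi)` with binary weights (the last band closes so the
extreme pair is counted); by default 10 equal-width bands to the maximum
pairwise distance. Bands without pairs carry NA. An optional two-sided
permutation test (off by default) shuffles values over cells; the p-value
uses the observed-included rank convention.

## The spatial-lag model

`y = ρWy + Xβ + ε`, `ε ~ N(0, σ²I)`, fitted by profile maximum likelihood
over ρ: `β(ρ)` and `σ²(ρ)` have closed forms, and
`ℓ(ρ) = −(n/2)(ln 2π + ln σ²(ρ) + 1) + Σᵢ ln(1 − ρλᵢ)` uses the precomputed
eigenvalues of W. Conventions:

- **Weights** reuse the GWR kernel (the inherent autocorrelation of GWR
  outputs lives at the kernel scale), with zero diagonal and row
  standardization by default, so λ_max = 1 and ρ is searched in
  (1/λ_min, 1) by bounded scalar minimization (tolerance 1e−8). A raw
  symmetric-kernel option is retained for sensitivity runs. Eigenvalues of
  the row-standardized matrix are obtained from the similar symmetric form
  `D^(−1/2)KD^(−1/2)`, guaranteeing a real spectrum.
- **Inference on β** is conditional on ρ̂ (`σ̂²(XᵀX)⁻¹` with two-sided
  z-tests) — the common first-order approximation. The full information
  matrix would widen the β standard errors slightly; at the significance
  level used downstream (p < 0.05 flags on standardized slopes) the choice
  is immaterial, and it is recorded in run metadata.
- ρ̂ within 1e−6 of an interval boundary sets `converged_ = False`.

## Latitudinal trend tests

Each response and |latitude| are z-scored *within* the hemisphere subset, so
slopes are standardized and a positive slope means increase away from the
equator. OLS uses a two-sided t-test; the spatial-lag fit rebuilds its
weights on the hemisphere's cells only (hemispheres are analyzed
separately, so cross-hemisphere neighbors are cut). No multiple-testing
correction is applied: each cell of the 4-response × 2-hemisphere ×
4-kernel summary is read as a single test, and the pattern of signs — not
any single p-value — carries the inference. At least 10 usable cells are
required per fit.

## The synthetic-data generator

The generator emulates the statistical structure of a tropical/subtropical
richness grid: ~34°N–33°S at 1° resolution (default 67 × 24 = 1608 cells,
matching the ~1500-cell scale of real palm grids), richness peaking near
the equator, two internally correlated climate sets, and climate–richness
coefficients that vary with |latitude|:

    richness = round(max(0, a + β_w(φ)·W + β_e(φ)·E + ε)),
    β_w(φ) = b_w0 − b_w1|φ|,   β_e(φ) = b_e0 + b_e1|φ|,

where W and E are the z-scored first principal axes of the water and energy
triples (computed by the generator itself). Driving richness through the
composites — rather than a single variable — makes the full 3-variable
model the correct all-subsets answer, and a rounded truncated-linear
response (not a count distribution) matches the Gaussian regression model
the pipeline fits; a Poisson option is noted as future work.

Climate fields are a linear |latitude| trend plus unit-variance spatially
smoothed noise (white noise convolved with a Gaussian distance kernel,
smoothing range 150 km by default). The smoothing range is deliberately
well below the GWR bandwidth: a 1200-km window then contains many
independent noise patches, so *local* water–energy correlations concentrate
near their target rather than wandering freely (with a 500-km range a
window sees ~2 patches and local correlations are essentially arbitrary).
Within-set correlation comes from a shared latent field per set (default
loading 0.8); the cross-set correlation is tuned toward `rho_we` through a
latent shared between sets, with an analytic first-order correction for the
attenuation the composites introduce. Trend intercepts/slopes and noise sds
are set to realistic magnitudes (e.g. AP 2400 − 50·|φ| ± 350 mm/yr, MAT
26.5 − 0.28·|φ| ± 2.5 °C) chosen so that physical floors (non-negative
precipitation and water deficit) rarely bind — binding floors distort local
variances with latitude and contaminate null scenarios. AET is
back-computed as PET − WD so the pipeline's derived deficit reproduces the
generated field. Default effect sizes (a = 60, b_w0 = 32, b_e0 = 4,
b_w1 = b_e1 = 0.8 species per unit composite per degree, noise sd 8
species) give equator richness ≈ 100 falling to near zero at the grid edge,
and local R² in the 0.4–0.9 range — comparable to real megathermal plant
grids.

Presets: `predictor_shift` (the effect under test), `collinear`
(`rho_we = 0.8`), `shift_with_sac` (adds 600-km spatially autocorrelated
richness errors), and `stationary` — the null control, which zeroes both
the coefficient gradients *and* the climate fields' latitude trends.  The
latter matters: with climate trends present, boundary-truncated edge
windows give the local R² surface a true, reproducible latitude trend even
under constant coefficients, so a "stationary" scenario with trends would
not actually embody the null hypothesis the control is meant to test.

**What the generator does not emulate:** real coastline geometry (land
fraction is drawn uniformly on [0.3, 1], independent of location),
dispersal limitation and evolutionary history, non-Gaussian richness error,
anisotropic climate structure, and observation error in range maps.
Passing tests therefore validate the statistical machinery under the
assumed data-generating model, not the biological conclusions one would
draw from real data.

## Null behavior and known limitations

- **OLS trend tests on GWR outputs are anticonservative by construction.**
  Local results of overlapping windows are inherently autocorrelated; on a
  grid spanning only a few bandwidths the local-R² surface carries roughly
  (extent/bandwidth)² independent values, while the OLS t-test assumes one
  per cell. Under the stationary null the measured rejection rate at
  α = 0.05 is ~0.9, not 0.05 — which is precisely why the pipeline pairs
  every OLS trend with a spatial-lag fit (whose rejection rate under the
  same null is no higher, as the acceptance suite asserts). OLS slopes are
  reported for comparability, but only the SAR fits support calibrated
  inference.
- **Edge effects.** Even under the null, truncated edge windows overfit the
  richer combined model slightly more than the 3-variable models, giving
  mean null slopes for R_w / R_pe of magnitude up to ~0.2 (against a
  seed-to-seed spread of ~0.5). Trend estimates within a bandwidth of the
  grid edge should be read with this in mind.
- **Spatial-lag ρ̂ near 1.** On smooth local-R² responses ρ̂ is typically
  0.98–0.999; this is expected (the response is nearly a local average of
  itself), but it means SAR slope magnitudes are not comparable to OLS
  magnitudes — only their signs and significance are.
- **Problem sizes in the test suite.** Multi-seed simulation tests use the
  full-extent grid at reduced longitudinal width (67 × 8 cells) or the full
  1608-cell grid for the headline predictor-shift check; these sizes were
  chosen so the suite exercises realistic latitudinal structure while
  remaining quick to run.
- Dense n × n matrices are used throughout (distance, kernel, eigenvalue
  computations); this is comfortable at the ~1500-cell scale the package
  targets but would need sparse machinery well beyond ~10⁴ cells.
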