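"""Seeded generator of palm-like gridded richness datasets.

The generator emulates the statistical structure the analysis pipeline
assumes: a contiguous 1-degree grid spanning the tropics/subtropics
(~34N to ~33S), species richness peaking near the equator, two internally
correlated climate-variable sets (water: AP, MPDM, WD; energy: MAT, MTCM,
PET) with a tunable cross-set correlation, and climate–richness coefficients
that vary with absolute latitude:

    mu_i       = a + beta_w(phi_i) * W_i + beta_e(phi_i) * E_i + eps_i
    beta_w(phi) = b_w0 - b_w1 |phi|       (water influence fades poleward)
    beta_e(phi) = b_e0 + b_e1 |phi|       (energy influence grows poleward)
    richness_i  = round(max(0, mu_i))

W and E are the z-scored first principal axes of the water and energy
variable triples, computed by the generator itself.  Climate fields are a
deterministic |latitude| trend plus spatially smoothed Gaussian noise (white
noise convolved with a Gaussian distance kernel), with within-set
correlation induced by a shared latent field per set and cross-set
correlation by a latent shared between sets.

Because the coefficient surfaces are known by construction, the generator
doubles as a recovery oracle for the GWR estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spatial_weights import distance_matrix_km


@dataclass(frozen=True)
class ClimateFieldSpec:
    """One climate variable: linear |lat| trend plus correlated noise.

    ``loading`` is the weight on the variable set's shared latent field
    (sign gives the direction of association within the set); the remainder
    is idiosyncratic smoothed noise.  ``floor`` clips physically impossible
    values (e.g. negative precipitation).
    """

    intercept: float
    lat_slope: float  # per degree of |lat|
    sd: float
    loading: float = 0.8
    floor: float | None = None


_DEFAULT_FIELDS: dict[str, ClimateFieldSpec] = {
    # water set (mm/yr, mm/month, mm)
    "AP": ClimateFieldSpec(2400.0, -50.0, 350.0, loading=0.8, floor=0.0),
    "MPDM": ClimateFieldSpec(120.0, -2.0, 28.0, loading=0.8, floor=0.0),
    "WD": ClimateFieldSpec(150.0, 12.0, 80.0, loading=-0.8, floor=0.0),
    # energy set (degC, degC, mm/yr)
    "MAT": ClimateFieldSpec(26.5, -0.28, 2.5, loading=0.8),
    "MTCM": ClimateFieldSpec(21.0, -0.5, 3.5, loading=0.8),
    "PET": ClimateFieldSpec(1650.0, -14.0, 180.0, loading=0.8, floor=100.0),
}

WATER_FIELD_NAMES = ("AP", "MPDM", "WD")
ENERGY_FIELD_NAMES = ("MAT", "MTCM", "PET")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one synthetic study."""

    lat_range: tuple[float, float] = (-33.0, 34.0)
    lon_range: tuple[float, float] = (-81.0, -57.0)
    cell_size_deg: float = 1.0
    fields: dict[str, ClimateFieldSpec] = field(default_factory=lambda: dict(_DEFAULT_FIELDS))
    smoothing_range_km: float = 150.0   # spatial range of climate noise fields
    rho_we: float = 0.3                 # target water-energy cross-correlation
    # coefficient surfaces: beta_w = b_w0 - b_w1*|lat|, beta_e = b_e0 + b_e1*|lat|
    b_w0: float = 32.0
    b_w1: float = 0.8
    b_e0: float = 4.0
    b_e1: float = 0.8
    baseline: float = 60.0              # richness at W = E = 0
    noise_sd: float = 8.0               # richness error sd (species)
    error_range_km: float = 0.0         # 0 = i.i.d. richness errors
    seed: int = 0

    def __post_init__(self):
        if not -1 < self.rho_we < 1:
            raise ValueError("rho_we must lie in (-1, 1)")
        if self.b_w1 < 0 or self.b_e1 < 0:
            raise ValueError("b_w1 and b_e1 must be >= 0")
        if self.cell_size_deg <= 0:
            raise ValueError("cell_size_deg must be positive")


def _grid_centers(config: ScenarioConfig) -> tuple[np.ndarray, np.ndarray]:
    step = config.cell_size_deg
    lat0, lat1 = config.lat_range
    lon0, lon1 = config.lon_range
    lats = np.arange(lat0 + step / 2, lat1, step)
    lons = np.arange(lon0 + step / 2, lon1, step)
    if len(lats) < 2 or len(lons) < 2:
        raise ValueError("degenerate grid: need at least 2 rows and 2 columns")
    glon, glat = np.meshgrid(lons, lats)
    return glat.ravel(), glon.ravel()


def _smooth_field(rng: np.random.Generator, dmat: np.ndarray,
                  range_km: float) -> np.ndarray:
    """Unit-variance spatially smoothed Gaussian field (white noise
    convolved with a Gaussian distance kernel of the stated range)."""
    z = rng.standard_normal(dmat.shape[0])
    if range_km > 0:
        k = np.exp(-0.5 * (dmat / range_km) ** 2)
        z = k @ z
    z = z - z.mean()
    sd = z.std(ddof=1)
    return z / sd if sd > 0 else z


def generate_cells(config: ScenarioConfig) -> pd.DataFrame:
    """Generate the climate-only cell table (no richness yet).

    Within-set correlations come from one shared latent field per variable
    set; the cross-set correlation is tuned toward ``rho_we`` through a
    latent shared between the two sets.  AET is back-computed from the
    generated water deficit (AET = PET - WD), so the pipeline's derived
    WD reproduces the generated field.
    """
    rng = np.random.default_rng(config.seed)
    lat, lon = _grid_centers(config)
    n = lat.size
    dmat = distance_matrix_km(lat, lon)
    r = config.smoothing_range_km

    # Shared latents with target cross-correlation.  The composite indices
    # dilute the set latent with idiosyncratic noise, attenuating the
    # realized cross-correlation by roughly the product of the per-set
    # latent-composite correlations; compensate when mixing the latents.
    f_common = _smooth_field(rng, dmat, r)
    f_water = _smooth_field(rng, dmat, r)
    f_energy = _smooth_field(rng, dmat, r)

    def _attenuation(names):
        alphas = np.array([abs(config.fields[v].loading) for v in names])
        k = len(names)
        abar = alphas.mean()
        return abar / np.sqrt(abar**2 + np.sum(1 - alphas**2) / k**2)

    rho = np.clip(config.rho_we
                  / (_attenuation(WATER_FIELD_NAMES) * _attenuation(ENERGY_FIELD_NAMES)),
                  -0.99, 0.99)
    s = np.sign(rho) if rho != 0 else 1.0
    latent_w = np.sqrt(abs(rho)) * f_common + np.sqrt(1 - abs(rho)) * f_water
    latent_e = s * np.sqrt(abs(rho)) * f_common + np.sqrt(1 - abs(rho)) * f_energy

    abslat = np.abs(lat)
    cols: dict[str, np.ndarray] = {}
    for name, spec in config.fields.items():
        latent = latent_w if name in WATER_FIELD_NAMES else latent_e
        own = _smooth_field(rng, dmat, r)
        alpha = spec.loading
        noise = alpha * latent + np.sqrt(max(0.0, 1 - alpha**2)) * own
        v = spec.intercept + spec.lat_slope * abslat + spec.sd * noise
        if spec.floor is not None:
            v = np.maximum(v, spec.floor)
        cols[name] = v

    table = pd.DataFrame({
        "cell_id": [f"c{i:05d}" for i in range(n)],
        "lat_deg": lat,
        "lon_deg": lon,
        "land_fraction": rng.uniform(0.3, 1.0, n),
        "richness": np.zeros(n, dtype=int),  # filled by generate_richness
        "AP": cols["AP"], "MPDM": cols["MPDM"],
        "MAT": cols["MAT"], "MTCM": cols["MTCM"],
        "PET": cols["PET"],
    })
    table["AET"] = table["PET"] - cols["WD"]
    return table


def _pc1_scores(z: np.ndarray, align_with: np.ndarray) -> np.ndarray:
    """Z-scored first-principal-axis scores of a standardized matrix, sign
    aligned with a reference column."""
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    scores = z @ vt[0]
    if np.corrcoef(scores, align_with)[0, 1] < 0:
        scores = -scores
    scores = scores - scores.mean()
    return scores / scores.std(ddof=1)


def composite_indices(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """The water and energy composite indices (z-scored PC1 of each triple).

    WD is taken as PET - AET, matching what the analysis pipeline derives.
    """
    wd = (table["PET"] - table["AET"]).to_numpy(float)
    water = np.column_stack([table["AP"].to_numpy(float),
                             table["MPDM"].to_numpy(float), wd])
    energy = table[["MAT", "MTCM", "PET"]].to_numpy(float)

    def _z(m):
        return (m - m.mean(axis=0)) / m.std(axis=0, ddof=1)

    w_idx = _pc1_scores(_z(water), water[:, 0])   # align with AP: high = wet
    e_idx = _pc1_scores(_z(energy), energy[:, 0])  # align with MAT: high = warm
    return w_idx, e_idx


def detrended_cross_correlation(table: pd.DataFrame) -> float:
    """Correlation between the water and energy composites after removing
    their linear |latitude| trends — the quantity ``rho_we`` targets."""
    w_idx, e_idx = composite_indices(table)
    al = np.abs(table["lat_deg"].to_numpy(float))
    x = np.column_stack([np.ones_like(al), al])
    rw = w_idx - x @ np.linalg.lstsq(x, w_idx, rcond=None)[0]
    re = e_idx - x @ np.linalg.lstsq(x, e_idx, rcond=None)[0]
    return float(np.corrcoef(rw, re)[0, 1])


def generate_richness(cells: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Fill in richness from the latitude-varying coefficient model.

    Returns a copy of the table with the richness column set; the true
    coefficient surfaces and composite indices are attached as
    ``table.attrs["truth"]`` for recovery tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    w_idx, e_idx = composite_indices(cells)
    abslat = np.abs(cells["lat_deg"].to_numpy(float))
    beta_w = config.b_w0 - config.b_w1 * abslat
    beta_e = config.b_e0 + config.b_e1 * abslat

    n = len(cells)
    if config.error_range_km > 0:
        dmat = distance_matrix_km(cells["lat_deg"].to_numpy(float),
                                  cells["lon_deg"].to_numpy(float))
        eps = config.noise_sd * _smooth_field(rng, dmat, config.error_range_km)
    else:
        eps = config.noise_sd * rng.standard_normal(n)

    mu = config.baseline + beta_w * w_idx + beta_e * e_idx + eps
    richness = np.round(np.maximum(0.0, mu)).astype(int)
    if richness.max() == 0:
        raise ValueError("all-zero richness; baseline too aggressive")

    out = cells.copy()
    out["richness"] = richness
    out.attrs["truth"] = {
        "beta_w": beta_w, "beta_e": beta_e,
        "W": w_idx, "E": e_idx, "mu": mu,
    }
    return out


def generate_dataset(config: ScenarioConfig) -> pd.DataFrame:
    """Climate plus richness in one call."""
    return generate_richness(generate_cells(config), config)


SCENARIOS = ("stationary", "predictor_shift", "shift_with_sac", "collinear")


def scenario(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Named preset configurations.

    - ``stationary``: constant coefficients (b_w1 = b_e1 = 0), i.i.d. errors,
      and *flat* climate fields (no deterministic latitude trends), so local
      explained variance has no true latitudinal structure at all — the
      null control for the trend tests.
    - ``predictor_shift``: water influence falls and energy influence rises
      with |latitude| (the effect the analysis is meant to detect).
    - ``shift_with_sac``: predictor_shift plus spatially autocorrelated
      richness errors.
    - ``collinear``: predictor_shift with strongly correlated water and
      energy sets (rho_we = 0.8).
    """
    flat_fields = {name: replace(spec, lat_slope=0.0)
                   for name, spec in _DEFAULT_FIELDS.items()}
    presets = {
        "stationary": dict(b_w0=25.0, b_w1=0.0, b_e0=10.0, b_e1=0.0,
                           fields=flat_fields),
        "predictor_shift": dict(),
        "shift_with_sac": dict(error_range_km=600.0),
        "collinear": dict(rho_we=0.8),
    }
    if name not in presets:
        raise ValueError(f"unknown scenario {name!r}; valid names: {SCENARIOS}")
    params = {**presets[name], "seed": seed, **overrides}
    return replace(ScenarioConfig(), **params)
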