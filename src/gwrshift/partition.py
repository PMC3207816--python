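"""Per-cell variation partitioning of local explained variance.

For each grid cell the local R^2 of the best water model (R_w), the best
energy model (R_e) and their combined model (R_t) are decomposed into

    pure water   R_pw   = R_t - R_e
    pure energy  R_pe   = R_t - R_w
    shared       shared = R_w + R_e - R_t

Because the three fits are nested weighted least-squares problems sharing
the same per-cell weights, R_t >= max(R_w, R_e) holds algebraically, so the
pure fractions are non-negative up to floating-point noise; a genuine
negative indicates an internal inconsistency and is raised, not clamped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gwr import GWRFit

#: magnitude below which a negative pure fraction is treated as round-off
_CLAMP_TOL = 1e-9


def partition_local(fit_water: GWRFit, fit_energy: GWRFit,
                    fit_combined: GWRFit) -> pd.DataFrame:
    """Partition local explained variance cell by cell.

    The three fits must cover the same cells with the same kernel, and the
    combined predictors must contain both the water and energy predictors.
    Cells unreliable in any fit carry NA.  Returns a table with columns
    ``cell_id, lat_deg, lon_deg, R_w, R_e, R_t, R_pw, R_pe, shared``.
    """
    for other in (fit_energy, fit_combined):
        if not np.array_equal(fit_water.cell_ids, other.cell_ids):
            raise ValueError("cell sets differ between fits")
        if other.kernel != fit_water.kernel:
            raise ValueError("kernel mismatch between fits")
    need = set(fit_water.predictors.members) | set(fit_energy.predictors.members)
    if not need <= set(fit_combined.predictors.members):
        raise ValueError("combined model does not nest water and energy predictors")

    r_w = fit_water.local_r2.copy()
    r_e = fit_energy.local_r2.copy()
    r_t = fit_combined.local_r2.copy()
    ok = fit_water.reliable & fit_energy.reliable & fit_combined.reliable
    for arr in (r_w, r_e, r_t):
        arr[~ok] = np.nan

    r_pw = r_t - r_e
    r_pe = r_t - r_w
    for frac in (r_pw, r_pe):
        neg = frac < 0
        if np.any(frac[neg & np.isfinite(frac)] < -_CLAMP_TOL):
            worst = np.nanmin(frac)
            raise ValueError(
                f"negative pure fraction {worst:.3e} exceeds round-off; "
                "fits are not nested as assumed"
            )
        frac[neg & np.isfinite(frac)] = 0.0
    shared = r_t - r_pw - r_pe  # == r_w + r_e - r_t up to the clamping above

    return pd.DataFrame({
        "cell_id": fit_water.cell_ids,
        "lat_deg": fit_water.lat_deg,
        "lon_deg": fit_water.lon_deg,
        "R_w": r_w, "R_e": r_e, "R_t": r_t,
        "R_pw": r_pw, "R_pe": r_pe, "shared": shared,
    })


#: the four per-cell responses analyzed against latitude downstream
RESPONSES = ("R_w", "R_e", "R_pw", "R_pe")
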