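"""Latitudinal trends in local explained variance — the headline test.

Each per-cell response (total water R_w, total energy R_e, pure water R_pw,
pure energy R_pe) is regressed on absolute latitude, separately per
hemisphere, with both plain OLS and a lagged SAR whose weights reuse the GWR
kernel.  Response and |latitude| are z-scored within the hemisphere subset,
so slopes are standardized; a positive slope means the quantity increases
away from the equator.  The water–energy shift hypothesis predicts
slope(R_pw) < 0 and slope(R_pe) > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cell_data import zscore
from .partition import RESPONSES
from .sar import fit_sar_lag
from .spatial_weights import KernelSpec, build_weights

HEMISPHERES = ("north", "south")
METHODS = ("ols", "sar")

MIN_CELLS = 10


@dataclass(frozen=True)
class TrendResult:
    response: str
    hemisphere: str
    method: str
    kernel: KernelSpec
    slope: float
    p_value: float
    n_cells: int
    rho: float | None = None
    converged: bool = True

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _hemisphere_subset(partition: pd.DataFrame, hemisphere: str,
                       response: str) -> pd.DataFrame:
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
    mask = partition["lat_deg"] >= 0 if hemisphere == "north" else partition["lat_deg"] < 0
    sub = partition.loc[mask & partition[response].notna()]
    if len(sub) < MIN_CELLS:
        raise ValueError(
            f"only {len(sub)} usable cells in the {hemisphere} hemisphere "
            f"for {response}; need >= {MIN_CELLS}"
        )
    return sub


def fit_latitudinal_trend(partition: pd.DataFrame, response: str,
                          hemisphere: str, method: str,
                          kernel: KernelSpec) -> TrendResult:
    """Standardized regression of one response on |latitude| in one hemisphere.

    ``method`` is ``"ols"`` (slope with a two-sided t-test) or ``"sar"``
    (lagged SAR; weights rebuilt on the hemisphere's cells only, with the
    GWR kernel's function and bandwidth, zero diagonal, row-standardized).
    """
    if response not in RESPONSES:
        raise ValueError(f"response must be one of {RESPONSES}")
    sub = _hemisphere_subset(partition, hemisphere, response)
    y = zscore(sub[response].to_numpy(float))
    x = zscore(np.abs(sub["lat_deg"].to_numpy(float)))

    if method == "ols":
        model = sm.OLS(y, sm.add_constant(x)).fit()
        return TrendResult(response, hemisphere, "ols", kernel,
                           slope=float(model.params[1]),
                           p_value=float(model.pvalues[1]),
                           n_cells=len(sub))
    if method == "sar":
        w = build_weights(sub, kernel, include_self=False, row_standardize=True)
        fit = fit_sar_lag(y, x[:, None], w)
        return TrendResult(response, hemisphere, "sar", kernel,
                           slope=float(fit.coef_[0]),
                           p_value=float(fit.p_values_[1]),
                           n_cells=len(sub),
                           rho=float(fit.rho_),
                           converged=fit.converged_)
    raise ValueError(f"method must be one of {METHODS}")


def trend_grid(partition_by_kernel: dict[KernelSpec, pd.DataFrame],
               methods=METHODS) -> pd.DataFrame:
    """All response x hemisphere x kernel x method trend fits as a long table.

    With 4 responses, 2 hemispheres and 4 kernels this yields 32 rows per
    method.  ``significant`` flags p < 0.05 (no multiple-testing correction,
    by design: each cell of the summary is read as a single test).
    """
    rows = []
    for method in methods:
        for kernel, part in partition_by_kernel.items():
            for response in RESPONSES:
                for hemisphere in HEMISPHERES:
                    r = fit_latitudinal_trend(part, response, hemisphere, method, kernel)
                    rows.append({
                        "response": response,
                        "hemisphere": hemisphere,
                        "method": method,
                        "kernel": kernel.label,
                        "slope": r.slope,
                        "p_value": r.p_value,
                        "rho": r.rho,
                        "n_cells": r.n_cells,
                        "significant": r.significant,
                        "converged": r.converged,
                    })
    return pd.DataFrame(rows)


_RESPONSE_LABELS = {
    "R_e": "Energy (total)", "R_pe": "Energy (pure)",
    "R_w": "Water (total)", "R_pw": "Water (pure)",
}


def trend_table(grid: pd.DataFrame, method: str) -> pd.DataFrame:
    """Pivot one method's trends into the Model / Hemisphere x kernel layout."""
    sub = grid.loc[grid["method"] == method].copy()
    sub["Model"] = sub["response"].map(_RESPONSE_LABELS)
    sub["Hemisphere"] = sub["hemisphere"].str.capitalize()
    wide = sub.pivot_table(index=["Model", "Hemisphere"], columns="kernel",
                           values="slope", sort=False)
    wide.columns.name = None
    return wide.reset_index()
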