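"""Great-circle distances, spatial kernels, and weight matrices.

The same two kernel families drive both the geographically weighted
regressions and the spatial-lag models:

* ``bisquare`` — :math:`w(d) = (1 - (d/b)^2)^2` for ``d < b``, zero beyond;
  continuous and near-Gaussian within the bandwidth.
* ``moving_window`` — indicator kernel, weight 1 for ``d <= b``, zero beyond.

Distances are haversine great-circle distances between cell centers on a
sphere of radius 6371.0 km.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

KERNEL_FAMILIES = ("bisquare", "moving_window")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus bandwidth in km."""

    family: str
    bandwidth_km: float

    def __post_init__(self):
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(
                f"unknown kernel family {self.family!r}; choose from {KERNEL_FAMILIES}"
            )
        if not self.bandwidth_km > 0:
            raise ValueError("bandwidth_km must be positive")

    @property
    def label(self) -> str:
        return f"{self.family}-{self.bandwidth_km:g}"


#: The four kernel configurations used for the headline analysis.
DEFAULT_KERNELS = (
    KernelSpec("bisquare", 1200.0),
    KernelSpec("bisquare", 1800.0),
    KernelSpec("moving_window", 1200.0),
    KernelSpec("moving_window", 1800.0),
)


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Haversine distance in km between points given in degrees.

    Broadcasts over array inputs; symmetric and non-negative.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(a, dtype=float) for a in (lat1, lon1, lat2, lon2))
    if not (np.all(np.isfinite(lat1)) and np.all(np.isfinite(lon1))
            and np.all(np.isfinite(lat2)) and np.all(np.isfinite(lon2))):
        raise ValueError("non-finite coordinates")
    if np.any(np.abs(lat1) > 90) or np.any(np.abs(lat2) > 90):
        raise ValueError("latitude out of [-90, 90]")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    return float(d) if d.ndim == 0 else d


def distance_matrix_km(lat_deg, lon_deg) -> np.ndarray:
    """Dense pairwise great-circle distance matrix (km) between cell centers."""
    lat = np.asarray(lat_deg, dtype=float)
    lon = np.asarray(lon_deg, dtype=float)
    d = great_circle_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(d, 0.0)
    return d


def kernel_weight(d_km, spec: KernelSpec):
    """Evaluate the kernel at distance(s) ``d_km``; weight in [0, 1].

    Bi-square is zero at and beyond the bandwidth; the moving window includes
    its boundary (weight 1 at ``d == b``).
    """
    d = np.asarray(d_km, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative distance")
    b = spec.bandwidth_km
    if spec.family == "bisquare":
        u = d / b
        w = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
    else:  # moving_window
        w = np.where(d <= b, 1.0, 0.0)
    return float(w) if w.ndim == 0 else w


@dataclass
class SpatialWeights:
    """An n x n kernel weight structure shared by GWR and SAR.

    ``matrix`` holds non-negative weights, zero beyond the bandwidth; it is
    symmetric before row standardization.  When ``row_standardized`` each row
    with at least one neighbor sums to 1.  The diagonal is zero when
    ``include_self`` is false.
    """

    matrix: np.ndarray
    kernel: KernelSpec
    row_standardized: bool
    include_self: bool

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def neighbor_counts(self) -> np.ndarray:
        m = self.matrix.copy()
        np.fill_diagonal(m, 0.0)
        return (m > 0).sum(axis=1)

    def to_edge_list(self) -> pd.DataFrame:
        """Sparse (i, j, w) edge-list representation of the nonzero weights."""
        i, j = np.nonzero(self.matrix)
        return pd.DataFrame({"i": i, "j": j, "w": self.matrix[i, j]})


def build_weights(
    cells: pd.DataFrame,
    spec: KernelSpec,
    include_self: bool = False,
    row_standardize: bool = False,
) -> SpatialWeights:
    """Pairwise kernel weights from great-circle distances between cells.

    Parameters
    ----------
    cells : DataFrame with ``lat_deg`` and ``lon_deg`` columns (>= 2 rows).
    include_self : keep weight 1 on the diagonal (GWR convention) or zero it
        (SAR / Moran convention).
    row_standardize : scale each row to sum 1.  Requested standardization
        with an isolated (neighborless) row is an error, signalling a
        bandwidth too small for the grid.
    """
    if len(cells) < 2:
        raise ValueError("need at least 2 cells")
    d = distance_matrix_km(cells["lat_deg"].to_numpy(), cells["lon_deg"].to_numpy())
    w = kernel_weight(d, spec)
    if not include_self:
        np.fill_diagonal(w, 0.0)
    if row_standardize:
        rowsum = w.sum(axis=1)
        isolated = np.flatnonzero(rowsum == 0)
        if len(isolated):
            raise ValueError(
                f"{len(isolated)} cell(s) have no neighbors within "
                f"{spec.bandwidth_km} km (rows {isolated[:10].tolist()}...); "
                "bandwidth too small for row standardization"
            )
        w = w / rowsum[:, None]
    return SpatialWeights(w, spec, row_standardize, include_self)
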