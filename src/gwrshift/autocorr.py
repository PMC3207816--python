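"""Moran's I and distance-band correlograms of per-cell surfaces.

Local GWR results are inherently spatially autocorrelated because nearby
focal cells share most of their local data.  The correlogram quantifies this:
Moran's I is computed in half-open great-circle distance bands [lo, hi), and
for smooth surfaces it is strongly positive at short range and decays on the
scale of the GWR bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spatial_weights import distance_matrix_km


def morans_i(values, weights) -> float:
    """Classical Moran's I: (n / S0) * (z' W z) / (z' z), z centered values.

    ``weights`` is an n x n non-negative matrix with zero diagonal and
    positive total S0.  Values must be non-constant (>= 3 observations).
    """
    z = np.asarray(values, float)
    w = np.asarray(weights, float)
    n = z.size
    if n < 3:
        raise ValueError("need at least 3 values")
    if w.shape != (n, n):
        raise ValueError("weights must be n x n")
    if np.any(np.diag(w) != 0):
        raise ValueError("weights must have a zero diagonal")
    s0 = w.sum()
    if s0 <= 0:
        raise ValueError("all-zero weights")
    z = z - z.mean()
    denom = z @ z
    if denom == 0:
        raise ValueError("constant values have undefined Moran's I")
    return float((n / s0) * (z @ w @ z) / denom)


@dataclass
class Correlogram:
    """Moran's I per distance band; bins with no pairs carry NA."""

    bin_edges: np.ndarray  # length nbins + 1, km, ascending
    morans_i: np.ndarray
    pair_count: np.ndarray  # ordered pairs (i != j) per bin
    p_value: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "bin_lo": self.bin_edges[:-1],
            "bin_hi": self.bin_edges[1:],
            "morans_i": self.morans_i,
            "pairs": self.pair_count,
        })
        out["p"] = self.p_value if self.p_value is not None else np.nan
        return out


def correlogram(values, cells: pd.DataFrame, bin_edges=None, n_bins: int = 10,
                n_permutations: int = 0, rng=None) -> Correlogram:
    """Moran's I correlogram over great-circle distance bands.

    Bands are half-open [lo, hi); by default ``n_bins`` equal-width bands up
    to the maximum pairwise distance (the last band is closed so the extreme
    pair is counted).  ``n_permutations > 0`` adds a two-sided permutation
    p-value per band from random relabelling of the values over cells.
    """
    z = np.asarray(values, float)
    keep = np.isfinite(z)
    z = z[keep]
    lat = cells["lat_deg"].to_numpy(float)[keep]
    lon = cells["lon_deg"].to_numpy(float)[keep]
    d = distance_matrix_km(lat, lon)

    if bin_edges is None:
        dmax = d.max()
        bin_edges = np.linspace(0.0, dmax, n_bins + 1)
    bin_edges = np.asarray(bin_edges, float)
    if len(bin_edges) < 3:
        raise ValueError("need at least 2 distance bins")
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly ascending")

    nb = len(bin_edges) - 1
    stat = np.full(nb, np.nan)
    pairs = np.zeros(nb, int)
    pvals = np.full(nb, np.nan) if n_permutations else None
    rng = np.random.default_rng(rng)

    off_diag = ~np.eye(len(z), dtype=bool)
    for k in range(nb):
        lo, hi = bin_edges[k], bin_edges[k + 1]
        inband = (d >= lo) & ((d < hi) | ((k == nb - 1) & (d <= hi)))
        w = np.where(inband & off_diag, 1.0, 0.0)
        pairs[k] = int(w.sum())
        if pairs[k] == 0:
            continue
        stat[k] = morans_i(z, w)
        if n_permutations:
            null = np.empty(n_permutations)
            for b in range(n_permutations):
                null[b] = morans_i(rng.permutation(z), w)
            # two-sided rank p with the observed value included
            extreme = np.sum(np.abs(null) >= abs(stat[k]))
            pvals[k] = (extreme + 1) / (n_permutations + 1)

    return Correlogram(bin_edges, stat, pairs, pvals)
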