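"""Gridded cell-table handling: loading, validation, filtering, derived variables.

The unit of analysis is a 1°x1° grid cell carrying species richness and six
climate variables.  Two predictor sets are distinguished throughout the
package: a *water* set (annual precipitation AP, minimum precipitation of the
driest month MPDM, water deficit WD) and an *energy* set (mean annual
temperature MAT, minimum temperature of the coldest month MTCM, potential
evapotranspiration PET).  Water deficit is derived as WD = PET - AET; AET
itself is never used as a predictor because it confounds water and energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns every input table must provide (AET may be absent once WD exists).
SCHEMA_COLUMNS = (
    "cell_id", "lat_deg", "lon_deg", "land_fraction", "richness",
    "AP", "MPDM", "MAT", "MTCM", "PET", "AET",
)

CLIMATE_COLUMNS = ("AP", "MPDM", "MAT", "MTCM", "PET", "AET")

WATER_VARIABLES = ("AP", "MPDM", "WD")
ENERGY_VARIABLES = ("MAT", "MTCM", "PET")


@dataclass(frozen=True)
class VariableSet:
    """A named, ordered set of predictor columns.

    ``name`` is one of ``"water"``, ``"energy"`` or ``"combined"``;
    ``members`` must be drawn from the corresponding climate variables and
    contain no duplicates.
    """

    name: str
    members: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"duplicate members in variable set {self.name!r}")
        allowed = {
            "water": set(WATER_VARIABLES),
            "energy": set(ENERGY_VARIABLES),
            "combined": set(WATER_VARIABLES) | set(ENERGY_VARIABLES),
        }
        if self.name not in allowed:
            raise ValueError(f"unknown variable-set name {self.name!r}")
        extra = set(self.members) - allowed[self.name]
        if extra:
            raise ValueError(
                f"variable set {self.name!r} may not contain {sorted(extra)}"
            )


WATER_SET = VariableSet("water", WATER_VARIABLES)
ENERGY_SET = VariableSet("energy", ENERGY_VARIABLES)


class SchemaError(ValueError):
    """Input table does not conform to the cell-table contract."""


@dataclass
class FilterReport:
    """Counts of cells removed by each filtering rule."""

    n_input: int = 0
    n_low_land: int = 0
    n_missing_climate: int = 0
    n_kept: int = 0
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_low_land": self.n_low_land,
            "n_missing_climate": self.n_missing_climate,
            "n_kept": self.n_kept,
            "notes": list(self.notes),
        }


def load_cell_table(path) -> pd.DataFrame:
    """Read and validate a cell table CSV.

    The CSV must carry a header with all schema columns.  Missing values may
    be encoded as empty fields or ``NA``.  Row order is preserved.

    Raises
    ------
    SchemaError
        On a missing column, non-numeric value, out-of-range latitude or
        duplicate cell id.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    return validate_cell_table(df)


def validate_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory cell table against the schema contract."""
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns and c != "AET"]
    if "AET" not in df.columns and "WD" not in df.columns:
        missing.append("AET")
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    df = df.copy()
    numeric_cols = [c for c in df.columns if c != "cell_id"]
    for col in numeric_cols:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"non-numeric value in column {col!r}: {exc}") from None

    bad_lat = df.index[df["lat_deg"].abs() > 90]
    if len(bad_lat):
        raise SchemaError(f"latitude out of [-90, 90] at row(s) {list(bad_lat)}")
    bad_lon = df.index[df["lon_deg"].abs() > 360]
    if len(bad_lon):
        raise SchemaError(f"longitude out of range at row(s) {list(bad_lon)}")

    if df["cell_id"].duplicated().any():
        dupes = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
        raise SchemaError(f"duplicate cell_id values: {dupes}")
    if df.duplicated(subset=["lat_deg", "lon_deg"]).any():
        raise SchemaError("duplicate (lat_deg, lon_deg) cell centers")

    lf = df["land_fraction"]
    if ((lf < 0) | (lf > 1)).any():
        raise SchemaError("land_fraction outside [0, 1]")

    rich = df["richness"].dropna()
    if (rich < 0).any():
        raise SchemaError("negative richness")
    if not np.allclose(rich, np.round(rich)):
        raise SchemaError("richness must be integer-valued")
    return df


def filter_cells(
    table: pd.DataFrame,
    min_land: float = 0.25,
    report: FilterReport | None = None,
) -> pd.DataFrame:
    """Apply the standard cell filters.

    Cells with *less than* ``min_land`` land surface are excluded (a cell at
    exactly ``min_land`` is retained), as are cells with any missing climate
    value — typically coastal cells falling outside the climate rasters.
    """
    if report is None:
        report = FilterReport()
    report.n_input = len(table)

    keep_land = table["land_fraction"] >= min_land
    report.n_low_land = int((~keep_land).sum())

    climate = [c for c in CLIMATE_COLUMNS if c in table.columns]
    if "WD" in table.columns:
        climate.append("WD")
    keep_climate = table[climate].notna().all(axis=1)
    report.n_missing_climate = int((keep_land & ~keep_climate).sum())

    out = table.loc[keep_land & keep_climate].copy()
    report.n_kept = len(out)
    if report.n_kept == 0:
        raise ValueError("all cells removed by filtering; nothing to analyze")
    return out


def derive_water_deficit(table: pd.DataFrame) -> pd.DataFrame:
    """Add the water-deficit column WD = PET - AET (mm).

    AET is retained in the table but is not a predictor.  A negative deficit
    (AET > PET, an aggregation artifact in coarse rasters) is permitted with
    a warning.
    """
    for col in ("PET", "AET"):
        if col not in table.columns:
            raise SchemaError(f"cannot derive WD: column {col!r} missing")
    out = table.copy()
    out["WD"] = out["PET"] - out["AET"]
    if (out["WD"].dropna() < 0).any():
        warnings.warn(
            "negative water deficit (AET > PET) in some cells; "
            "likely a raster-aggregation artifact",
            stacklevel=2,
        )
    return out


def zscore(values) -> np.ndarray:
    """Standardize to mean 0 and sample (n-1 denominator) standard deviation 1."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = x.std(ddof=1)
    # relative guard: arrays of identical large values can have a tiny
    # nonzero sd from float round-off and must count as constant
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, np.abs(x).max()):
        raise ValueError("cannot standardize a constant input")
    return (x - x.mean()) / sd


def split_hemispheres(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition cells by hemisphere of the cell center.

    Latitude >= 0 goes north (with 1° cells centered at half-degrees the
    boundary case never arises on real grids).  The two outputs are disjoint
    and their union is the input.
    """
    north = table.loc[table["lat_deg"] >= 0]
    south = table.loc[table["lat_deg"] < 0]
    return north.copy(), south.copy()
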