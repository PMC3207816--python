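import numpy as np
import pandas as pd
import pytest

import gwrshift as g
from gwrshift.cell_data import ENERGY_SET, WATER_SET
from gwrshift.gwr import combined_model, fit_gwr
from gwrshift.partition import partition_local

# a reduced study grid (41 x 8 = 328 cells) keeping the full latitudinal
# logic but cheap enough for per-test GWR fits
SMALL_GRID = dict(lat_range=(-20.0, 21.0), lon_range=(-75.0, -67.0))

KERNEL_1200 = g.KernelSpec("bisquare", 1200.0)


@pytest.fixture(scope="session")
def shift_table():
    """Filtered predictor-shift cell table on the reduced grid."""
    cfg = g.scenario("predictor_shift", seed=3, **SMALL_GRID)
    tab = g.generate_dataset(cfg)
    return g.filter_cells(g.derive_water_deficit(tab)).reset_index(drop=True)


@pytest.fixture(scope="session")
def shift_fits(shift_table):
    """Full water / energy / combined GWR fits at the 1200-km bi-square kernel."""
    fw = fit_gwr(shift_table, WATER_SET, KERNEL_1200)
    fe = fit_gwr(shift_table, ENERGY_SET, KERNEL_1200)
    fc = fit_gwr(shift_table, combined_model(WATER_SET, ENERGY_SET), KERNEL_1200)
    return {"water": fw, "energy": fe, "combined": fc}


@pytest.fixture(scope="session")
def partition_table(shift_fits):
    return partition_local(shift_fits["water"], shift_fits["energy"],
                           shift_fits["combined"])


@pytest.fixture()
def tiny_csv(tmp_path):
    """A minimal well-formed 3-cell table on disk."""
    df = pd.DataFrame({
        "cell_id": ["a", "b", "c"],
        "lat_deg": [0.5, 1.5, -0.5],
        "lon_deg": [-70.5, -70.5, -70.5],
        "land_fraction": [1.0, 0.8, 0.4],
        "richness": [40, 35, 50],
        "AP": [2000.0, 1800.0, 2200.0],
        "MPDM": [90.0, 80.0, 110.0],
        "MAT": [26.0, 25.5, 26.5],
        "MTCM": [21.0, 20.0, 22.0],
        "PET": [1500.0, 1450.0, 1550.0],
        "AET": [1300.0, 1200.0, 1400.0],
    })
    path = tmp_path / "cells.csv"
    df.to_csv(path, index=False)
    return path, df
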