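import numpy as np
import pandas as pd
import pytest

from allomass.core_data import COLUMNS, MeasurementTable, derive_variables
from allomass.simulate import SimulationConfig, simulate_allometric_table


def make_table(rows) -> MeasurementTable:
    """Build a MeasurementTable from dicts with defaults filled in."""
    defaults = {
        "class": "Mammalia",
        "clade": "other",
        "lifestyle": "terrestrial",
        "humerus_length_mm": 100.0,
        "humerus_circ_mm": 50.0,
        "femur_length_mm": 110.0,
        "femur_circ_mm": 55.0,
        "source": "test",
    }
    recs = []
    for i, row in enumerate(rows):
        rec = {"species": f"sp{i}", "body_mass_g": 1000.0, **defaults, **row}
        recs.append(rec)
    return MeasurementTable(pd.DataFrame(recs, columns=COLUMNS))


@pytest.fixture
def tiny_table() -> MeasurementTable:
    return make_table([
        {"species": "Aus bus", "body_mass_g": 5000.0},
        {"species": "Cus dus", "body_mass_g": 168_000_000.0 / 1000},
        {"species": "Eus fus", "body_mass_g": 250.0, "humerus_circ_mm": np.nan},
    ])


@pytest.fixture(scope="session")
def sim_table() -> MeasurementTable:
    """Study-scale synthetic dataset under the default conditions."""
    return simulate_allometric_table(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def noiseless_table() -> MeasurementTable:
    return simulate_allometric_table(
        SimulationConfig(seed=7, sigma=0.0, target_R2=None, slope=3.0, intercept=-1.1)
    )
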