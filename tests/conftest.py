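"""Shared fixtures for the aidcycle test suite."""

import numpy as np
import pandas as pd
import pytest

from aidcycle import hcs, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_cell_table(
    n: int = 60,
    seed: int = 0,
    nuclear_avg: float = 200.0,
    cyto_avg: float = 150.0,
    treatment: str = "untreated",
    time_hr: float = 0.0,
) -> pd.DataFrame:
    """A small well-formed observed cell table with controllable averages."""
    rng = np.random.default_rng(seed)
    nuc_area = rng.uniform(120, 200, n)
    cyto_area = rng.uniform(300, 450, n)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i:04d}" for i in range(n)],
            "construct": "AID-mCherry",
            "treatment": treatment,
            "time_hr": time_hr,
            "phase_true": rng.choice(["G1", "S", "G2M"], size=n),
            "nuclear_area": nuc_area,
            "cyto_area": cyto_area,
            "cell_area": nuc_area + cyto_area,
            "nuclear_total": nuclear_avg * nuc_area * rng.uniform(0.8, 1.2, n),
            "cyto_total": cyto_avg * cyto_area * rng.uniform(0.8, 1.2, n),
            "dapi_total": rng.uniform(90, 210, n),
        }
    )


@pytest.fixture
def cell_table():
    return make_cell_table()


@pytest.fixture
def quantified_small():
    """A small gated, phase-assigned, averaged population for summary tests."""
    cells = make_cell_table(n=120, seed=3)
    cells = hcs.compute_compartment_averages(cells)
    return hcs.assign_phase(cells)


@pytest.fixture
def zero_noise_mm():
    return simulate.MeasurementModel(noise_cv=0.0)
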