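import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("deterministic")

from carbmsi import (IsotopeTable, MSIDataset, default_scenario, demo_db,
                     simulate_paired)

# Independent isotope-mass oracle: values transcribed from a second published
# atomic-mass table at its own precision, used only to cross-check masses.
ORACLE_MASSES = {
    "H": 1.007825032,
    "C": 12.0,
    "N": 14.003074005,
    "O": 15.994914620,
    "P": 30.973761998,
    "S": 31.972071174,
    "Br": 78.918338,
}
ORACLE_ELECTRON = 0.000548580


def oracle_mass(counts: dict[str, int]) -> float:
    return sum(n * ORACLE_MASSES[el] for el, n in counts.items())


@pytest.fixture(scope="session")
def table():
    return IsotopeTable.default()


@pytest.fixture(scope="session")
def db():
    return demo_db()


@pytest.fixture(scope="session")
def scenario():
    return default_scenario()


@pytest.fixture(scope="session")
def paired_seed7(scenario):
    """The default co-culture pair at seed 7, shared across tests."""
    layout, panel, noise = scenario
    plus, minus, truth = simulate_paired(layout, panel, noise, seed=7)
    return plus, minus, truth


def make_dataset(peaks, width=4, height=3, **kw):
    frame = pd.DataFrame(peaks, columns=["x", "y", "mz", "intensity"])
    return MSIDataset(width, height, frame, **kw)


@pytest.fixture
def tiny_dataset():
    """2 pixels, 3 centroids — deterministic hand-checkable grid."""
    return make_dataset([(0, 0, 400.0000, 10.0),
                         (0, 0, 500.0, 5.0),
                         (1, 1, 400.0012, 2.0)])
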