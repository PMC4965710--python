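import numpy as np
import pandas as pd
import pytest

from ehrweights.ehr_data import CohortTable, EventTable
from ehrweights.synthetic_ehr import SimulationConfig, generate_cohort
from ehrweights.temporal_features import WindowGrid


@pytest.fixture
def grid():
    return WindowGrid()


@pytest.fixture
def tiny_events():
    """Hand-built three-patient event table."""
    df = pd.DataFrame(
        {
            "patient": ["p1", "p1", "p1", "p2", "p2", "p3"],
            "code": ["X", "X", "X", "Y", "X", "Z"],
            "type": ["drug", "drug", "drug", "diagnosis", "drug", "measurement"],
            "day_offset": [1, 1, 5, 0, 30, 90],
        }
    )
    return EventTable(df, horizon=90)


@pytest.fixture
def tiny_cohort():
    return CohortTable(pd.DataFrame({"patient": ["p1", "p2", "p3"], "label": [1, 0, 1]}))


def small_config(**overrides):
    """A fast small-cohort configuration for unit tests."""
    defaults = dict(
        n_patients=200,
        n_codes_per_type={"diagnosis": 20, "drug": 20, "measurement": 20},
        n_informative=4,
        effect_multiplier=5.0,
        baseline_rate=0.3,
        positive_fraction=0.3,
        seed=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic cohort shared across tests (seed 17)."""
    cfg = small_config(seed=17)
    events, cohort, truth = generate_cohort(cfg)
    return cfg, events, cohort, truth


@pytest.fixture(scope="session")
def default_dataset():
    """One default-scale synthetic cohort (600 patients, 1500 codes)."""
    cfg = SimulationConfig(seed=29)
    events, cohort, truth = generate_cohort(cfg)
    return cfg, events, cohort, truth


def rng_event_table(rng: np.random.Generator, n_patients=6, n_codes=4, n_events=40, horizon=90):
    """Random well-formed event table for property tests."""
    patients = [f"p{i}" for i in range(n_patients)]
    codes = [(f"C{j}", ["diagnosis", "drug", "measurement"][j % 3]) for j in range(n_codes)]
    rows = []
    for _ in range(n_events):
        p = patients[rng.integers(n_patients)]
        c, t = codes[rng.integers(n_codes)]
        rows.append((p, c, t, int(rng.integers(0, horizon + 1))))
    df = pd.DataFrame(rows, columns=["patient", "code", "type", "day_offset"])
    cohort = CohortTable(
        pd.DataFrame({"patient": patients, "label": [i % 2 for i in range(n_patients)]})
    )
    return EventTable(df, horizon=horizon), cohort
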