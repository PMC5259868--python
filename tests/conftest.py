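import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from texsurv.cohort import build_patient_table, extract_lesion_table
from texsurv.synthetic import SimulationConfig, gen_cohort


@pytest.fixture(scope="session")
def demo_cohort():
    """A small imaged cohort with known generating parameters."""
    config = SimulationConfig(n_patients=20, seed=7)
    records, truth = gen_cohort(config)
    return config, records, truth


@pytest.fixture(scope="session")
def patient_table(demo_cohort):
    """End-to-end patient-level analysis table for the demo cohort."""
    _, records, _ = demo_cohort
    lesion_features = extract_lesion_table(records)
    return build_patient_table(records, lesion_features)


@pytest.fixture
def toy_cox_data():
    """8 patients, untied times, one continuous covariate (frozen)."""
    times = np.array([5.0, 8.0, 12.0, 16.0, 20.0, 25.0, 30.0, 34.0])
    events = np.array([1, 1, 0, 1, 1, 0, 1, 1])
    x = np.array([0.5, 1.2, -0.3, 0.8, -1.1, 0.4, -0.6, -1.0])
    return times, events, x
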