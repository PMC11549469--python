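import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from braincog.datatypes import CohortTable, FeatureBlock
from braincog.synthetic import SimulationConfig, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_cohort() -> CohortTable:
    """Six-subject cohort covering both sexes and all diagnoses."""
    return CohortTable(
        pd.DataFrame(
            {
                "subject_id": [f"P{i}" for i in range(6)],
                "cohort": "TEST",
                "site": ["a", "a", "a", "b", "b", "b"],
                "age": [50.0, 55.0, 60.0, 65.0, 70.0, 75.0],
                "sex": ["male", "female", "male", "female", "male", "female"],
                "diagnosis": ["HC", "HC", "HC", "HC", "MCI", "AD"],
                "education": [10.0, 12.0, 14.0, 16.0, 12.0, 10.0],
            }
        )
    )


@pytest.fixture
def planted_cohort():
    """Mid-size cohort with a strong planted mode, for recovery checks."""
    cfg = SimulationConfig(n_subjects=300, mode_strength=1.0, beta_age=0.5, seed=123)
    return simulate_cohort(cfg)


def make_block(values, kind="brain", prefix="f"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return FeatureBlock(
        [f"S{i}" for i in range(n)], [f"{prefix}{j}" for j in range(p)], values, kind
    )
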