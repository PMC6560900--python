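import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import lymphcoo as lc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_df():
    """Six hand-written cases covering both classes and a missing value."""
    return pd.DataFrame(
        {
            "case_id": ["P1", "P2", "P3", "P4", "P5", "P6"],
            "CD10": [90.0, 0.0, 0.0, 5.0, 80.0, 0.0],
            "BCL6": [0.0, 0.0, 70.0, 10.0, 90.0, np.nan],
            "FOXP1": [10.0, 90.0, 20.0, 85.0, 5.0, 95.0],
            "GCET1": [5.0, 0.0, 70.0, 10.0, 90.0, 0.0],
            "MUM1": [0.0, 90.0, 10.0, 80.0, 0.0, 85.0],
            "gep_label": ["GCB", "ABC", "GCB", "UC", "GCB", "ABC"],
            "os_months": [50.0, 10.0, 40.0, 5.0, 60.0, 12.0],
            "os_event": [0, 1, 0, 1, 0, 1],
        }
    )


@pytest.fixture
def tiny_cohort(tiny_df):
    return lc.Cohort(tiny_df, provenance="tiny")


@pytest.fixture(scope="session")
def sim_cohort_475():
    """Study-sized synthetic cohort under the default conditions."""
    return lc.simulate_cohort(lc.default_config(n=475, seed=11))


@pytest.fixture(scope="session")
def sim_cohort_large():
    """Large synthetic cohort for calibration/recovery checks."""
    return lc.simulate_cohort(lc.default_config(n=10_000, seed=12))
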