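import numpy as np
import pandas as pd
import pytest

from coxladder import derivation_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest derivation-like cohort shared across tests."""
    return generate_cohort(derivation_config(n_patients=600, seed=42))


@pytest.fixture(scope="session")
def medium_cohort():
    return generate_cohort(derivation_config(n_patients=2000, seed=7))


@pytest.fixture
def toy_survival():
    """Eight patients, one covariate, distinct times, mixed censoring."""
    return pd.DataFrame(
        {
            "x": [0.5, -1.2, 0.3, 2.0, -0.7, 1.1, 0.0, -0.4],
            "time_years": [1.0, 2.0, 2.5, 3.0, 4.0, 5.0, 6.5, 8.0],
            "event": [1, 0, 1, 1, 0, 1, 1, 0],
        }
    )
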