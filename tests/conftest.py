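import numpy as np
import pytest

from amcsuite import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """500 cases / 2000 controls, 10 predictors, moderate tail effect."""
    return generate_cohort(SimConfig(n_cases=500, control_ratio=4, n_predictors=10, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
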