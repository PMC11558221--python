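import numpy as np
import pandas as pd
import pytest

from keyphen import CohortConfig, MixtureParams, generate_cohort

PAPER_PARAMS = MixtureParams(
    means=np.array([0.112, 0.180, 0.268]),
    sigma=0.048,
    weights=np.array([0.375, 0.544, 0.081]),
)


@pytest.fixture(scope="session")
def fitted_params() -> MixtureParams:
    """The 3-class mixture at its published point estimates."""
    return PAPER_PARAMS


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (128 subjects, ~23 days each)."""
    return generate_cohort(CohortConfig(), seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
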