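import numpy as np
import pytest

from conntraj.design import build_design
from conntraj.synthetic import generate_covariates


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def covariates_600():
    """Medium cohort: 600 subjects, ages 8-100, six sites."""
    return generate_covariates(600, seed=7)


@pytest.fixture(scope="session")
def design_600(covariates_600):
    return build_design(
        covariates_600["age"].to_numpy(), covariates_600["sex"].to_numpy()
    )
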