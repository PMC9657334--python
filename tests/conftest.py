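import numpy as np
import pytest

from surromark.simulate import CohortParams, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    return generate_cohort(CohortParams(n_samples=750, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
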