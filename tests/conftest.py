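import numpy as np
import pytest

from cxrtriage import CohortSpec, generate_cohort, make_validation_fixture


@pytest.fixture(scope="session")
def default_cohort():
    """Default-sized synthetic cohort (1045 studies, published structure)."""
    return generate_cohort(CohortSpec(seed=1234))


@pytest.fixture(scope="session")
def edge_cohort():
    """Small deterministic cohort with missing labels, ties and extreme rows."""
    return make_validation_fixture(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
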