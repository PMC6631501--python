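import numpy as np
import pytest

import rsmann as rm


@pytest.fixture(scope="session")
def factors():
    return rm.load_factors()


@pytest.fixture(scope="session")
def ccrd_data():
    """The 27-run five-level CCRD with measured yields."""
    return rm.load_fixture("table2")


@pytest.fixture(scope="session")
def validation_data():
    """The 4 external validation runs."""
    return rm.load_fixture("table4")


@pytest.fixture(scope="session")
def fitted_model(ccrd_data):
    return rm.fit_quadratic(ccrd_data)


@pytest.fixture(scope="session")
def fitted_anova(fitted_model, ccrd_data):
    return rm.anova(fitted_model, ccrd_data)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240817)
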