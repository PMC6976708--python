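import numpy as np
import pytest

import survgain as sg


@pytest.fixture(scope="session")
def low_cohort():
    """A mid-size low-heterogeneity cohort with 20% censoring."""
    scen = sg.make_scenario("low")
    return sg.simulate_cohort(scen, n=600, p_censor=0.2, seed=42)


@pytest.fixture(scope="session")
def low_cohort_ps(low_cohort):
    return sg.fit_ps(low_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
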