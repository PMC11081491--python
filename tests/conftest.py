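import numpy as np
import pytest

import wagework as ww


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """12 subjects simulated from the alpha update+maintenance+fa model."""
    spec = ww.ModelSpec.parse("alpha:update+maintenance+fa")
    sessions, truth = ww.simulate_cohort(12, spec, np.random.default_rng(77))
    return spec, sessions, truth


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """Single-model hierarchical fit of the small cohort (raw ratings)."""
    spec, sessions, _ = small_cohort
    cohort = [ww.subject_data_from_session(s, rating_kind="raw") for s in sessions]
    fit = ww.fit_hierarchical(
        [spec], cohort, ww.FitConfig(), np.random.default_rng(78)
    )
    return spec, cohort, fit
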