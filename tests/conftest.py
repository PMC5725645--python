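import numpy as np
import pandas as pd
import pytest

from gutphase.config import default_config
from gutphase.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject cohort for fast end-to-end checks."""
    return simulate_cohort(default_config(seed=7, n_subjects=12))


@pytest.fixture(scope="session")
def default_cohort():
    """The default 95-subject study-condition cohort."""
    return simulate_cohort(default_config(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture()
def lms_chart():
    from gutphase.io import synthetic_lms_chart

    return synthetic_lms_chart()
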