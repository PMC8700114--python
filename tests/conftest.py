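import numpy as np
import pytest

from hrvibs import compute_index_table, generate_cohort


@pytest.fixture(scope="session")
def short_cohort():
    """Small labelled cohort of 30-min records for fast end-to-end checks."""
    return generate_cohort(6, 6, seed=11, duration=1800.0)


@pytest.fixture(scope="session")
def short_index_table(short_cohort):
    return compute_index_table(short_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
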