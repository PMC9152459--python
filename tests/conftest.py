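import numpy as np
import pytest

from thermohrv import synthetic as syn


@pytest.fixture(scope="session")
def strong_cohort():
    """32-subject cohort at the default (strong) coupling and noise."""
    return syn.generate_cohort(n=32, master_seed=1)


@pytest.fixture(scope="session")
def null_cohort():
    """32-subject cohort with zero thermal-HRV coupling."""
    return syn.generate_cohort(n=32, master_seed=2, coupling=syn.CouplingParams.null())


@pytest.fixture(scope="session")
def small_cohort():
    """12-subject cohort for cheaper smoke checks."""
    return syn.generate_cohort(n=12, master_seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rr_ms(rng, n=None):
    """A physiologically plausible random RR series in ms."""
    if n is None:
        n = int(rng.integers(30, 121))
    return rng.uniform(600.0, 1200.0, size=n)
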