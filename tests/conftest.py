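import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

from cropshock import compose_region, florida_fixture, run_sweep


@pytest.fixture()
def florida():
    return florida_fixture()


@pytest.fixture()
def florida_region(florida):
    """30-unit Florida region with 2 diversified units."""
    return compose_region(30, 2, florida)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def florida_sweep():
    """The full 14 x (10 intensities x 10 durations) Florida sweep, shared by
    the experiment-level tests (runs once per session, a few seconds)."""
    return run_sweep(florida_fixture())
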