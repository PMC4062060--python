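import numpy as np
import pytest

from methprog.synthetic import (
    SimConfig,
    default_design,
    simulate_cohort,
    simulate_reference,
)


@pytest.fixture(scope="session")
def ref():
    """Default synthetic reference, shared across tests (read-only)."""
    return simulate_reference(SimConfig(), seed=7)


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def cohort(ref, design):
    return simulate_cohort(ref, design, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
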