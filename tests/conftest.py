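import numpy as np
import pytest
from hypothesis import settings

from aonsim import (
    Schedule,
    default_genotypes,
    default_grid_levels,
    default_signalling,
    run_simulation,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture()
def registry():
    return default_genotypes()


@pytest.fixture()
def signalling():
    return default_signalling()


@pytest.fixture()
def grid_levels():
    return default_grid_levels()


@pytest.fixture()
def schedule():
    return Schedule()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def baseline_runs():
    """Shared seed-1 baseline runs: unregulated mutant and wild-type
    reference (both measured at days 10 and 16)."""
    reg = default_genotypes()
    sched = Schedule()
    nt = run_simulation("nts1116", None, schedule=sched, seed=1, registry=reg)
    br = run_simulation(
        "bragg", default_signalling(), schedule=sched, seed=1, registry=reg
    )
    return nt, br
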