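import numpy as np
import pytest

from pulsetim import DoseSchedule, preset


@pytest.fixture(scope="session")
def table2():
    """Baseline therapy-study parameter set, antigenicity 0.1."""
    return preset("table2", beta=0.1)


@pytest.fixture(scope="session")
def section4():
    """Therapy-study set with T cell death rate 0.02/day (threshold studies)."""
    return preset("section4", beta=0.1)


@pytest.fixture(scope="session")
def fig2():
    """Slow-growth set for the no-treatment bifurcation study."""
    return preset("fig2", beta=0.1)


@pytest.fixture(scope="session")
def weekly():
    return DoseSchedule(d_cd4=0.0, d_il4=0.0, tau=7.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20170911)
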