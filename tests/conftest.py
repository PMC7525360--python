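import numpy as np
import pytest

from mwimhi import SequenceParams, T2Grid, make_toy_fixture


@pytest.fixture(scope="session")
def seq():
    """Default 48-echo, 8 ms echo-spacing train."""
    return SequenceParams()


@pytest.fixture(scope="session")
def grid():
    """Default 40-point logarithmic T2 grid, 15 ms – 2 s."""
    return T2Grid()


@pytest.fixture(scope="session")
def toy():
    """Deterministic miniature phantom + cohort used across tests."""
    return make_toy_fixture()


@pytest.fixture(scope="session")
def two_pool_curve(seq):
    """Noiseless 15% myelin / 85% IE decay curve at 180° refocusing."""
    from mwimhi import multi_compartment_curve

    return multi_compartment_curve(
        [(0.15, 0.02, 1.0), (0.85, 0.08, 1.0)], 180.0, seq
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
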