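import numpy as np
import pytest

import ltphrcharts as lc


@pytest.fixture
def rng():
    return np.random.default_rng(20250922)


@pytest.fixture(scope="session")
def expo():
    return lc.exponential()


@pytest.fixture(scope="session")
def gamma_uni():
    return lc.gamma_uniform()


@pytest.fixture(scope="session")
def worked_example():
    return lc.load_fixture("worked_example")


@pytest.fixture(scope="session")
def mouse_ic():
    """In-control parameters of the mouse-lifetime example."""
    return lc.ICSpec(0.9587, 0.5444)
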