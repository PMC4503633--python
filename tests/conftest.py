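import logging

import numpy as np
import pytest

from confent.spaces import MetricSpace

# estimator warnings (duplicates, unbinned rotations) are expected in
# several degenerate-input tests; keep the log quiet
logging.getLogger("confent").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def torus2():
    return MetricSpace.torus([2.0 * np.pi, 2.0 * np.pi])


@pytest.fixture(scope="session")
def circle():
    return MetricSpace.torus([2.0 * np.pi])


@pytest.fixture(scope="session")
def rotation_space():
    return MetricSpace.rotation()
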