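import numpy as np
import pytest

import mvarnet as mn


@pytest.fixture(scope="session")
def small_net():
    """A small stable random network with mildly correlated inputs."""
    conn = mn.generate_connectivity("random", n=5, density=0.5, w_min=0.1, w_max=0.3, seed=11)
    sigma = mn.generate_input_covariance(5, 0.1, seed=11)
    return conn, sigma


@pytest.fixture(scope="session")
def small_panel(small_net):
    conn, sigma = small_net
    return mn.simulate(conn, sigma, 4000, seed=7)


@pytest.fixture(scope="session")
def white_panel():
    """Independent white-noise nodes (null network)."""
    rng = np.random.default_rng(123)
    return mn.TimeSeriesPanel(rng.standard_normal((6, 3000)))
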