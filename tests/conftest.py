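import numpy as np
import pytest

import emonet as em


@pytest.fixture(scope="session")
def three_node_net():
    w = np.array([[0.0, 0.4, 0.2], [0.4, 0.0, 0.0], [0.2, 0.0, 0.0]])
    return em.ComponentNetwork(("a", "b", "c"), w, np.array([-1.0, -0.5, 0.3]))


@pytest.fixture(scope="session")
def small_net():
    """Mild random 6-node network: mixes quickly, enumerable exactly."""
    return em.random_network(6, seed=42)


@pytest.fixture(scope="session")
def fear_net():
    return em.make_fixture_network("fear_like", seed=0)


@pytest.fixture(scope="session")
def awe_net():
    return em.make_fixture_network("awe_like", seed=0)


@pytest.fixture(scope="session")
def short_schedule():
    return em.EventSchedule(
        baseline_sweeps=30, amplitude=2.0, hold_sweeps=10, fade_sweeps=20,
        post_sweeps=60,
    )
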