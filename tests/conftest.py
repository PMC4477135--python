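import numpy as np
import pytest

from triplenet import NetworkAtlas, NodeSpec, SimulationConfig, default_atlas, simulate_cohort


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture()
def rng():
    return np.random.default_rng(20150609)


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort for fast unit tests; study-scale runs live in acceptance tests."""
    return SimulationConfig(n_per_group=6, n_timepoints=120, seed=11)


@pytest.fixture(scope="session")
def small_cohort(atlas, small_config):
    return simulate_cohort(atlas, small_config)


@pytest.fixture(scope="session")
def tiny_atlas():
    """Three well-separated nodes in two networks, for geometry round trips."""
    return NetworkAtlas(
        [
            NodeSpec("a", "N1", 0, 0, 0, radius=3),
            NodeSpec("b", "N1", 20, 0, 0, radius=3),
            NodeSpec("c", "N2", 0, 20, 0, radius=3),
        ]
    )
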