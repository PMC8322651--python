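import numpy as np
import pytest

from cgsterol.synthetic import (
    default_ground_truth,
    generate_membrane,
    simulate_trajectory,
)


@pytest.fixture(scope="session")
def small_gt():
    """Desk-scale ground truth shared by fast tests."""
    return default_ground_truth(n_per_leaflet=32, n_frames=150, seed=1234)


@pytest.fixture(scope="session")
def small_traj(small_gt):
    return simulate_trajectory(generate_membrane(small_gt), small_gt)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
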