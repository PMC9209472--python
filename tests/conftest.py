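"""Shared fixtures: small synthetic sessions with known ground truth."""

import numpy as np
import pytest

from placecode.behavior import analyze_behavior
from placecode.synthetic_data import (
    SimulationConfig,
    render_session,
    simulate_population,
    simulate_trajectory,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(duration_s=600.0, n_cells=40, rng_seed=11)


@pytest.fixture(scope="session")
def small_render(small_config):
    gt = simulate_population(small_config, 11)
    traj = simulate_trajectory(small_config, 12)
    return gt, traj, render_session(gt, traj, small_config, 13)


@pytest.fixture(scope="session")
def small_session(small_render):
    return small_render[2].session


@pytest.fixture(scope="session")
def small_behavior(small_session):
    return analyze_behavior(small_session)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
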