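"""Shared fixtures: preset trajectories are expensive, so they are
simulated once per session (4 s, fixed-step RK4 at 0.1 ms) and reused."""

import numpy as np
import pytest

from bgtcsim import SimulationConfig, load_preset, simulate, summarize
from bgtcsim.sweeps import SWEEP_SIM_CONFIG


@pytest.fixture(scope="session")
def preset_trajectories():
    return {name: simulate(load_preset(name), SWEEP_SIM_CONFIG)
            for name in ("healthy", "tremor", "beta")}


@pytest.fixture(scope="session")
def preset_summaries(preset_trajectories):
    return {name: summarize(traj, include_phase=True)
            for name, traj in preset_trajectories.items()}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
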