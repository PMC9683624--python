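import numpy as np
import pytest

from rdconnectome import (
    Connectome,
    SolverConfig,
    Trajectory,
    mechanosensory_fixture,
)


@pytest.fixture(scope="session")
def fixture_connectome() -> Connectome:
    return mechanosensory_fixture(seed=0)


@pytest.fixture
def two_node_chain() -> Connectome:
    return Connectome.from_edges([("A", "B", 1.0)])


@pytest.fixture
def symmetric_pair() -> Connectome:
    return Connectome.from_edges([("A", "B", 1.0), ("B", "A", 1.0)])


def sinusoid_trajectory(phases, n=400, periods=4, species=("U", "V")):
    """Trajectory of unit sinusoids with given per-node phases."""
    t = np.linspace(0, 2 * np.pi * periods, n, endpoint=False)
    X = np.stack([np.sin(t + ph) for ph in phases])
    states = np.stack([X, X])
    return Trajectory(
        times=t,
        states=states,
        species=species,
        nodes=[f"n{i}" for i in range(len(phases))],
    )


@pytest.fixture
def quick_solver() -> SolverConfig:
    return SolverConfig(method="rk4", dt=0.1, n_steps=200, seed=1)
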