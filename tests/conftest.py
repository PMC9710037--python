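import numpy as np
import pytest

from boolsde import (
    ProteinNode,
    SignalingNetwork,
    SimulationConfig,
    StimulusSchedule,
    Trajectory,
    WeightedEdge,
    build_mapk_fixture,
)


@pytest.fixture
def mapk():
    return build_mapk_fixture()


@pytest.fixture
def chain3():
    """Smallest chain A -> B -> C with weights set."""
    return SignalingNetwork(
        [ProteinNode("A"), ProteinNode("B"), ProteinNode("C")],
        [WeightedEdge("A", "B", 0.5), WeightedEdge("B", "C", 0.5)],
    )


@pytest.fixture
def fast_config():
    """Reduced-resolution profile: same t in [0, 60] horizon as the
    reference dt=0.001 / 60,000-step grid."""
    return SimulationConfig(dt=0.01, n_steps=6000, seed=0)


def decay_pair(weight: float = 0.5) -> SignalingNetwork:
    """Two-node receptor->sink network whose receptor decays at rate
    ``k_d * weight`` — the closed-form exponential test problem."""
    return SignalingNetwork(
        [ProteinNode("A"), ProteinNode("B")],
        [WeightedEdge("A", "B", weight)],
    )


def make_trajectory(times, columns: dict) -> Trajectory:
    """Hand-built trajectory for statistics tests."""
    times = np.asarray(times, dtype=float)
    node_order = list(columns)
    activities = np.column_stack([np.asarray(columns[n], float) for n in node_order])
    return Trajectory(
        times=times,
        activities=activities,
        node_order=node_order,
        config=SimulationConfig(dt=float(times[1] - times[0]), n_steps=len(times) - 1),
        schedule=StimulusSchedule(),
        seed=0,
    )
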