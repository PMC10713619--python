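import numpy as np
import pytest
from hypothesis import settings

import groupchase as gc
from groupchase.core import Mode, Strategy

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def table1_config():
    """The published operating point (mixed model, v_D = 0.082)."""
    return gc.SimulationConfig(model="B", v_D=0.082, seed=0)


@pytest.fixture
def small_config():
    """Dense small habitat for fast engine-level tests (captures occur
    within a few hundred steps)."""
    return gc.SimulationConfig(
        model="C", v_D=0.082, N_C=25, N_T=12, R=25.0, r_haz=8.0,
        r_learn=10.0, T_max=800, seed=7)


def make_world(chaser_pos, target_pos, strategies=None, modes=None,
               seed=0):
    """Hand-built world for kinematics tests."""
    chaser_pos = np.asarray(chaser_pos, dtype=float).reshape(-1, 2)
    target_pos = np.asarray(target_pos, dtype=float).reshape(-1, 2)
    n = len(chaser_pos)
    if strategies is None:
        strategies = [Strategy.DCS] * n
    if modes is None:
        modes = [Mode.HUNT] * n
    return gc.WorldState(
        t=0.0,
        chaser_pos=chaser_pos,
        chaser_strategy=np.array([int(s) for s in strategies], dtype=np.int8),
        chaser_mode=np.array([int(m) for m in modes], dtype=np.int8),
        t_hunt=np.zeros(n),
        t_rest=np.zeros(n),
        target_pos=target_pos,
        rng=np.random.default_rng(seed),
    )


@pytest.fixture
def make_world_fixture():
    return make_world
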