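import numpy as np
import pytest

from padock.docking import DockingConfig
from padock.oligomer import (OligomerSpec, build_oligomer,
                             substrate_nonbonded_table)
from padock.structures import assign_nonbonded
from padock.synthetic import (default_trajectory_truth, make_toy_complex,
                              make_trajectory)


@pytest.fixture(scope="session")
def channel_complex():
    structure, table = make_toy_complex("channel", seed=42)
    return assign_nonbonded(structure, table), table


@pytest.fixture(scope="session")
def wall_complex():
    structure, table = make_toy_complex("wall", seed=42)
    return assign_nonbonded(structure, table), table


@pytest.fixture(scope="session")
def dimer_conformer():
    conf = build_oligomer(OligomerSpec(2, "Ace", "COO_minus"))
    conf.structure = assign_nonbonded(conf.structure, substrate_nonbonded_table())
    return conf


@pytest.fixture(scope="session")
def small_config():
    return DockingConfig(n_samples=300, keep_k=20)


@pytest.fixture(scope="session")
def planted_trajectories():
    truth = default_trajectory_truth()
    trajs = make_trajectory(truth, n_frames=300, n_replicas=3, seed=7)
    return truth, trajs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
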