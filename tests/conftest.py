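import numpy as np
import pytest

from tmhkit import helix_geometry as hg
from tmhkit import synthetic_trajectory as st


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ideal_helix():
    return hg.build_ideal_helix("A" * 20)


@pytest.fixture(scope="session")
def ser_helix():
    return hg.build_ideal_helix("S" * 12)


@pytest.fixture(scope="session")
def scenario_labels():
    return st.scenario_label_map()


@pytest.fixture(scope="session")
def wt_run():
    """Small wild-type-like synthetic run shared across analysis tests."""
    spec = st.ScenarioSpec.preset("wt_like", n_frames=3000, seed=11)
    traj, truth = st.realize_coordinates(spec)
    return spec, traj, truth


@pytest.fixture(scope="session")
def mutant_run():
    spec = st.ScenarioSpec.preset("mutant_like", n_frames=3000, seed=11)
    traj, truth = st.realize_coordinates(spec)
    return spec, traj, truth


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
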