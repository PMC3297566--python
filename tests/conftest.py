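import numpy as np
import pytest

from pdznet import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_atoms():
    return synthetic.toy_topology()


@pytest.fixture(scope="session")
def markov_run():
    """A mid-size seeded run of the default (gated 4-state) generator."""
    spec = synthetic.default_trajectory_spec(n_frames=20_000, seed=7)
    traj, states = synthetic.gen_markov_trajectory(spec)
    return spec, traj, states


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniform random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
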