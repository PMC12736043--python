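import numpy as np
import pytest

from ligdyn.structio import AtomRecord, TrajectoryFrames
from ligdyn.synthdata import TrajectorySpec, gen_trajectory


@pytest.fixture(scope="session")
def default_traj():
    """The default study-condition trajectory (2000 frames) plus its truth."""
    return gen_trajectory(TrajectorySpec(seed=7))


@pytest.fixture(scope="session")
def small_traj():
    """A short trajectory for geometry tests."""
    return gen_trajectory(TrajectorySpec(seed=3, n_frames=40))[0]


def make_point_traj(coords, times=None, elements=None, names=None):
    """Build a bare trajectory from raw coordinates for geometric unit tests."""
    coords = np.asarray(coords, float)
    n_atoms = coords.shape[1]
    atoms = [AtomRecord(serial=i + 1,
                        atom_name=(names[i] if names else f"C{i+1}"),
                        element=(elements[i] if elements else "C"),
                        res_name="UNK", res_seq=1, chain_id="A")
             for i in range(n_atoms)]
    if times is None:
        times = np.arange(coords.shape[0], dtype=float)
    return TrajectoryFrames(atoms, coords, times)
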