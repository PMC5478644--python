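import numpy as np
import pytest

from deamscan.structio import Atom, Structure, Trajectory


def make_atom(serial, name, res_num, chain="A", res_name="GLY", coord=(0.0, 0.0, 0.0),
              element=None):
    from deamscan.structio import _infer_element

    return Atom(
        serial=serial,
        name=name,
        element=element or _infer_element(name),
        res_name=res_name,
        res_num=res_num,
        chain=chain,
        coord=tuple(coord),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_structure(rng):
    """30 CA atoms at random positions across 3 chains."""
    atoms = []
    serial = 1
    for chain in "ABC":
        for res in range(1, 11):
            atoms.append(
                make_atom(serial, "CA", res, chain=chain, coord=rng.uniform(-20, 20, 3))
            )
            serial += 1
    return Structure(atoms=atoms, title="random test structure")


def random_rigid_transform(rng):
    """A random proper rotation matrix and translation vector."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=int(rng.integers(2**31 - 1))).as_matrix(), rng.uniform(
        -30, 30, 3
    )


@pytest.fixture
def small_trajectory(random_structure, rng):
    frames = [random_structure.coords + rng.normal(0, 0.3, (len(random_structure), 3))
              for _ in range(5)]
    return Trajectory(topology=random_structure, frames=frames)
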