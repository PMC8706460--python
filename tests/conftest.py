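import numpy as np
import pytest

from grestkit.fixtures import make_mini_loop
from grestkit.model import SoluteSelection, ToySystem


@pytest.fixture(scope="session")
def mini_loop():
    """Default mini-loop fixture, shared across the suite."""
    return make_mini_loop()


@pytest.fixture(scope="session")
def mini_loop_small():
    """A cheaper mini-loop for smoke-level checks."""
    return make_mini_loop(n_framework=8, n_loop=6, gap_angle=2.6)


@pytest.fixture
def four_atom_system():
    """Four beads with one of every bonded term type plus nonbonded pairs."""
    pos = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                    [1.3, 1.0, 0.0], [2.0, 1.0, 1.0]])
    return ToySystem(
        positions=pos,
        masses=np.ones(4),
        charges=np.array([0.3, -0.3, 0.3, -0.3]),
        lj_eps=np.full(4, 0.5),
        lj_sigma=np.full(4, 0.9),
        bonds=np.array([[0, 1], [1, 2], [2, 3]]),
        bond_k=np.array([40.0, 40.0, 40.0]),
        bond_r0=np.array([1.0, 1.1, 1.2]),
        angles=np.array([[0, 1, 2], [1, 2, 3]]),
        angle_k=np.array([8.0, 8.0]),
        angle_theta0=np.array([1.9, 2.0]),
        dihedrals=np.array([[0, 1, 2, 3]]),
        dihedral_K=np.array([2.0]),
        dihedral_n=np.array([2]),
        dihedral_delta=np.array([np.pi]),
    )


def random_chain_system(rng: np.random.Generator, n_atoms: int = 6) -> ToySystem:
    """A randomized but valid chain system for property tests."""
    pos = np.zeros((n_atoms, 3))
    for i in range(1, n_atoms):
        step = rng.normal(size=3)
        pos[i] = pos[i - 1] + step / np.linalg.norm(step)
    pos += 0.05 * rng.normal(size=pos.shape)
    n_d = max(n_atoms - 3, 0)
    return ToySystem(
        positions=pos,
        masses=rng.uniform(0.5, 2.0, n_atoms),
        charges=rng.uniform(-0.5, 0.5, n_atoms),
        lj_eps=rng.uniform(0.0, 1.0, n_atoms),
        lj_sigma=rng.uniform(0.6, 1.1, n_atoms),
        bonds=np.array([[i, i + 1] for i in range(n_atoms - 1)]),
        bond_k=rng.uniform(20.0, 80.0, n_atoms - 1),
        bond_r0=rng.uniform(0.9, 1.1, n_atoms - 1),
        angles=np.array([[i, i + 1, i + 2] for i in range(n_atoms - 2)]),
        angle_k=rng.uniform(5.0, 20.0, n_atoms - 2),
        angle_theta0=rng.uniform(1.6, 2.4, n_atoms - 2),
        dihedrals=np.array([[i, i + 1, i + 2, i + 3] for i in range(n_d)]),
        dihedral_K=rng.uniform(0.2, 2.0, n_d),
        dihedral_n=rng.integers(1, 4, n_d),
        dihedral_delta=rng.uniform(0.0, 2 * np.pi, n_d),
    )


def random_selection(rng: np.random.Generator, n_atoms: int) -> SoluteSelection:
    size = int(rng.integers(1, n_atoms))
    atoms = rng.choice(n_atoms, size=size, replace=False)
    cats = [["dihedral"], ["vdw"], ["elec"], ["dihedral", "vdw"],
            ["vdw", "elec"], ["dihedral", "vdw", "elec"]]
    return SoluteSelection(atoms, cats[int(rng.integers(len(cats)))])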