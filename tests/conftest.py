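import numpy as np
import pytest

from pacqsar import AtomPropertyTable, Molecule
from pacqsar.synthetic import toy_molecule_suite


@pytest.fixture(scope="session")
def table():
    return AtomPropertyTable.default()


@pytest.fixture(scope="session")
def toys():
    return {m.id: m for m in toy_molecule_suite()}


def permute_molecule(mol: Molecule, perm: np.ndarray) -> Molecule:
    """Renumber atoms by perm (perm[new] = old)."""
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return Molecule(
        id=mol.id + "_perm",
        elements=tuple(mol.elements[j] for j in perm),
        bonds=tuple((int(inv[i]), int(inv[j]), o) for i, j, o in mol.bonds),
        coords=None if mol.coords is None else mol.coords[perm],
        implicit_h=tuple(mol.implicit_h[j] for j in perm),
        explicit_h=mol.explicit_h,
    )


def random_tree_molecule(rng: np.random.Generator, n: int) -> Molecule:
    """Random labelled tree over n carbon atoms with random bond orders."""
    bonds = []
    for i in range(1, n):
        j = int(rng.integers(0, i))
        order = float(rng.choice([1.0, 2.0, 3.0, 1.5]))
        bonds.append((j, i, order))
    return Molecule(id=f"tree{n}", elements=("C",) * n, bonds=tuple(bonds))
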