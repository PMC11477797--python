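"""Synthetic fixtures: toy molecules with hand-checkable descriptors and
regression datasets with known ground truth.

Everything the test suite and the examples need can be generated here, with
no external data: geometric toys (dimer, path, equilateral triangle, regular
tetrahedron) whose leverages, autocorrelations and eigenvalues can be worked
out on paper, a handful of real fused-ring aromatics parsed from SMILES, and
seeded Gaussian regression problems shaped like the published datasets
(62 compounds / 7 descriptors and 21 / 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_io import Molecule
from .modelbuild import QsarDataset
from .pipeline import MODEL_DESCRIPTORS


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth recipe for a synthetic regression dataset."""

    n: int
    p: int
    beta: tuple[float, ...]
    intercept: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.beta) != self.p:
            raise ValueError("beta must have length p")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _column_names(p: int) -> list[str]:
    """Descriptor names drawn from the real vocabulary, padded with D<k>."""
    names = list(MODEL_DESCRIPTORS[:p])
    names += [f"D{k}" for k in range(len(names), p)]
    return names


def generate_regression(spec: SyntheticSpec) -> QsarDataset:
    """X ~ iid standard normal, y = intercept + X beta + N(0, noise_sd²).

    Deterministic for a fixed spec (seeded generator); column names come from
    the real descriptor vocabulary so naming paths downstream are exercised.
    """
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.n, spec.p))
    y = spec.intercept + X @ np.asarray(spec.beta)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=spec.n)
    return QsarDataset(
        ids=tuple(f"cmpd{i:03d}" for i in range(spec.n)),
        X=pd.DataFrame(X, columns=_column_names(spec.p)),
        y=y,
    )


_EQ1_COEFS = np.array([10.29, -9.03, -0.50, -6.82, -5.58, -20.30, 2.43])
_EQ2_COEFS = np.array([-0.80, -33.75, 31.71])


def _scaled(coefs: np.ndarray, rmse: float, q2: float) -> tuple[float, ...]:
    """Scale a coefficient direction so that, with standard-normal descriptors
    and noise_sd = rmse, the population Q² equals the target.

    Var(signal) = rmse²·q2/(1−q2) for Q² = Var(signal)/(Var(signal)+rmse²),
    so the direction is rescaled to that squared norm.
    """
    signal_var = rmse**2 * q2 / (1.0 - q2)
    return tuple(coefs * np.sqrt(signal_var / np.sum(coefs**2)))


def model1_like_spec(seed: int = 0) -> SyntheticSpec:
    """A dataset emulating the non-halogenated study conditions: n=62, p=7.

    Coefficients keep the direction of the seven-descriptor activity
    equation but are rescaled, and the noise level set, so the population
    fit statistics match the published summary (Q² ≈ 0.80, RMSE ≈ 0.53).
    """
    return SyntheticSpec(
        n=62, p=7, beta=_scaled(_EQ1_COEFS, rmse=0.53, q2=0.80),
        intercept=-12.83, noise_sd=0.53, seed=seed,
    )


def model2_like_spec(seed: int = 0) -> SyntheticSpec:
    """A dataset emulating the halogenated study conditions: n=21, p=3
    (population Q² ≈ 0.89, RMSE ≈ 0.21)."""
    return SyntheticSpec(
        n=21, p=3, beta=_scaled(_EQ2_COEFS, rmse=0.21, q2=0.89),
        intercept=-3.34, noise_sd=0.21, seed=seed,
    )


# -- toy molecules -------------------------------------------------------

_SQ3 = np.sqrt(3.0)


def _toy(id_, elements, bonds, coords=None) -> Molecule:
    return Molecule(
        id=id_,
        elements=tuple(elements),
        bonds=tuple(bonds),
        coords=None if coords is None else np.asarray(coords, dtype=float),
    )


def chain2() -> Molecule:
    """Two bonded carbons (both terminal): the 2x2 Burden-matrix toy."""
    return _toy("chain2", ["C", "C"], [(0, 1, 1.0)], [[0, 0, 0], [1.54, 0, 0]])


def path4() -> Molecule:
    """Four-atom path graph: the hand-enumerable autocorrelation toy."""
    return _toy(
        "path4", ["C", "C", "C", "C"],
        [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)],
        [[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], [4.5, 0, 0]],
    )


def triangle() -> Molecule:
    """Equilateral triangle (side 1.5 Å): every leverage is exactly 2/3."""
    return _toy(
        "triangle", ["C", "C", "C"],
        [(0, 1, 1.0), (1, 2, 1.0), (2, 0, 1.0)],
        1.5 * np.array([[0, 0, 0], [1, 0, 0], [0.5, _SQ3 / 2, 0]]),
    )


def tetrahedron() -> Molecule:
    """Regular tetrahedron, fully bonded: every leverage is exactly 3/4."""
    coords = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) * 0.9
    bonds = [(i, j, 1.0) for i in range(4) for j in range(i + 1, 4)]
    return _toy("tetrahedron", ["C"] * 4, bonds, coords)


_AROMATIC_SMILES = {
    "benzene": "c1ccccc1",
    "naphthalene": "c1ccc2ccccc2c1",
    "fluorene": "C1c2ccccc2-c2ccccc21",
    "pyrene": "c1cc2ccc3cccc4ccc(c1)c2c34",
    "2-chloronaphthalene": "Clc1ccc2ccccc2c1",
    "2-bromonaphthalene": "Brc1ccc2ccccc2c1",
}


def toy_molecule_suite() -> list[Molecule]:
    """The fixed fixture set used throughout the descriptor tests.

    Geometric toys carry deterministic hardcoded coordinates; the aromatic
    molecules are parsed from SMILES (2D only — embed before 3D descriptors).
    The chloro/bromo naphthalenes exercise the halogen model-routing rule.
    """
    from rdkit import Chem

    from .chem_io import from_rdkit

    mols = [chain2(), path4(), triangle(), tetrahedron()]
    for name, smiles in _AROMATIC_SMILES.items():
        mols.append(from_rdkit(Chem.MolFromSmiles(smiles), name))
    return mols


def dataset_to_frame(data: QsarDataset, response: str = "y") -> pd.DataFrame:
    """Flatten a dataset to the CSV dialect the pipeline consumes."""
    df = data.X.copy()
    df.insert(0, "id", list(data.ids))
    df[response] = data.y
    if data.split is not None:
        df["split"] = list(data.split)
    return df
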