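"""Graph-based descriptors: Burden-matrix eigenvalues and 2D autocorrelations.

Both families are computed on the hydrogen-depleted graph with carbon-scaled
atomic property weights.  Only the sub-families the activity models need are
implemented — extreme Burden eigenvalues (SpMin/SpMax ranks), Moran and
centred Broto–Moreau autocorrelations — but each is fully parameterized over
(rank / lag, property weight), so e.g. SpMin2Bh(m), SpMax8Bh(i), MATS5s and
ATSC1e are all points of the same two functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_io import AtomPropertyTable, Molecule, atom_weights


@dataclass(frozen=True)
class BurdenConfig:
    """Off-diagonal constants of the Burden matrix.

    The classical formulation: bonded entries 0.1 x conventional bond order
    (aromatic 1.5), augmented by ``terminal_bonus`` for each bonded atom of
    heavy-degree 1, and ``nonbonded`` for all remaining off-diagonal entries.
    Exposed so the constants can be recalibrated against a reference
    descriptor engine.
    """

    bond_scale: float = 0.1
    terminal_bonus: float = 0.01
    nonbonded: float = 0.001


@dataclass(frozen=True)
class BurdenSpec:
    weight: str
    rank: int
    which: str  # "min" or "max"

    def __post_init__(self):
        if self.which not in ("min", "max"):
            raise ValueError(f"which must be 'min' or 'max', got {self.which!r}")
        if self.rank < 1:
            raise ValueError("rank must be a positive integer")


@dataclass(frozen=True)
class AutocorrSpec:
    family: str  # "moran" or "centred_broto_moreau"
    lag: int
    weight: str

    def __post_init__(self):
        if self.family not in ("moran", "centred_broto_moreau"):
            raise ValueError(f"unknown autocorrelation family {self.family!r}")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")


def burden_matrix(
    mol: Molecule,
    weight: str,
    table: AtomPropertyTable | None = None,
    config: BurdenConfig = BurdenConfig(),
) -> np.ndarray:
    """Symmetric Burden matrix on the hydrogen-depleted graph.

    Diagonal entries are the carbon-scaled property weights; bonded pairs get
    ``bond_scale * order`` plus ``terminal_bonus`` per degree-1 endpoint; all
    other off-diagonal entries are ``nonbonded``.
    """
    heavy = mol.heavy_indices()
    n = len(heavy)
    w = atom_weights(mol, weight, table, heavy_only=True)
    A = mol.adjacency(heavy_only=True)
    degree = (A > 0).sum(axis=1)
    B = np.full((n, n), config.nonbonded)
    np.fill_diagonal(B, w)
    for i in range(n):
        for j in range(i + 1, n):
            if A[i, j] > 0:
                val = config.bond_scale * A[i, j]
                if degree[i] == 1:
                    val += config.terminal_bonus
                if degree[j] == 1:
                    val += config.terminal_bonus
                B[i, j] = B[j, i] = val
    return B


def burden_eigenvalue(
    mol: Molecule,
    spec: BurdenSpec,
    table: AtomPropertyTable | None = None,
    config: BurdenConfig = BurdenConfig(),
) -> float:
    """``spec.rank``-th smallest (which=min) or largest (which=max) eigenvalue."""
    n = len(mol.heavy_indices())
    if n < spec.rank:
        raise ValueError(
            f"{mol.id}: Burden rank {spec.rank} requested but only {n} heavy atoms"
        )
    eig = np.linalg.eigvalsh(burden_matrix(mol, spec.weight, table, config))
    return float(eig[spec.rank - 1] if spec.which == "min" else eig[n - spec.rank])


def autocorrelation(
    mol: Molecule,
    spec: AutocorrSpec,
    table: AtomPropertyTable | None = None,
) -> float:
    """Centred Broto–Moreau (ATSC) or Moran (MATS) autocorrelation at a lag.

    With centred weights c_i = w_i - mean(w) over the A heavy atoms and pair
    set P_k = {(i,j): i<j, topological distance = k}:

    * ATSC_k = sum over P_k of c_i * c_j
    * MATS_k = [sum over P_k of c_i c_j / |P_k|] / [sum_i c_i^2 / A]

    Empty pair sets return 0; constant weights return 0 under Moran (the 0/0
    convention).  Pairs are counted once (i < j).
    """
    w = atom_weights(mol, spec.weight, table, heavy_only=True)
    D = mol.distance_matrix(heavy_only=True)
    return autocorrelation_from_weights(D, w, spec)


def autocorrelation_from_weights(
    distances: np.ndarray, weights: np.ndarray, spec: AutocorrSpec
) -> float:
    """Autocorrelation from an explicit distance matrix and weight vector."""
    w = np.asarray(weights, dtype=float)
    c = w - w.mean()
    iu, ju = np.triu_indices(len(w), k=1)
    at_lag = distances[iu, ju] == spec.lag
    if not at_lag.any():
        return 0.0
    cross = float(np.sum(c[iu[at_lag]] * c[ju[at_lag]]))
    if spec.family == "centred_broto_moreau":
        return cross
    variance = float(np.sum(c**2)) / len(w)
    if variance == 0.0:
        return 0.0
    return (cross / int(at_lag.sum())) / variance


def descriptor_name(spec: BurdenSpec | AutocorrSpec) -> str:
    """Canonical serialized name, e.g. ``SpMin2Bh(m)``, ``MATS5s``, ``ATSC1e``."""
    if isinstance(spec, BurdenSpec):
        stem = "SpMin" if spec.which == "min" else "SpMax"
        return f"{stem}{spec.rank}Bh({spec.weight})"
    prefix = "MATS" if spec.family == "moran" else "ATSC"
    return f"{prefix}{spec.lag}{spec.weight}"
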