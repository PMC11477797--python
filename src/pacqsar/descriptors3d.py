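"""Geometry-based descriptors: GETAWAY (HATS, H, HGM) and WHIM (E_m).

GETAWAY descriptors derive from the molecular influence matrix
H = M (M^T M)^+ M^T of centred atomic coordinates, whose diagonal entries
(atomic leverages) measure how far each atom sits from the molecular centre
along the principal directions.  WHIM descriptors come from a weighted
principal-component analysis of the same coordinates; the accessibility
index E_m is the inverse kurtosis of the atomic scores along axis m.

All descriptors here are computed on hydrogen-included structures and are
invariant under rigid motion and atom renumbering.  A tolerance-based
pseudoinverse keeps planar molecules — the common case for fused-ring
aromatics — on the ordinary code path (coordinate rank 2 instead of 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_io import AtomPropertyTable, Molecule, MoleculeError, atom_weights

#: singular values below RANK_TOL * max are treated as zero (planar/linear rank)
RANK_TOL = 1e-8


@dataclass(frozen=True)
class InfluenceMatrix:
    H: np.ndarray          # full A x A molecular influence matrix
    leverages: np.ndarray  # diagonal of H
    rank: int              # rank of the centred coordinate matrix (1, 2 or 3)


def influence_matrix(mol: Molecule) -> InfluenceMatrix:
    """Molecular influence matrix of the centred coordinates.

    Coordinates are centred at the (unweighted) geometric centroid; the
    projector H = M (M^T M)^+ M^T is built with a rank-revealing
    pseudoinverse so planar (rank 2) and linear (rank 1) molecules are
    handled exactly.  Leverages sum to the coordinate rank and lie in [0, 1].
    """
    if mol.coords is None:
        raise MoleculeError(f"{mol.id}: influence matrix requires 3D coordinates")
    if mol.n_atoms < 2:
        raise MoleculeError(f"{mol.id}: influence matrix needs at least 2 atoms")
    M = mol.coords - mol.coords.mean(axis=0)
    # H = U U^T over the non-null left singular subspace
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    keep = s > RANK_TOL * s.max() if s.max() > 0 else np.zeros_like(s, dtype=bool)
    Uk = U[:, keep]
    H = Uk @ Uk.T
    return InfluenceMatrix(H=H, leverages=np.diag(H).copy(), rank=int(keep.sum()))


def getaway_autocorrelation(
    mol: Molecule,
    kind: str,
    lag: int,
    weight: str,
    table: AtomPropertyTable | None = None,
) -> float:
    """Leverage (HATS) or influence (H) autocorrelation at a topological lag.

    Over atom pairs i < j at shortest-path distance ``lag``:

    * HATS_k(w) = sum (w_i h_i)(w_j h_j)          — leverage-weighted
    * H_k(w)    = sum w_i w_j h_ij  for h_ij > 0  — influence-weighted

    Returns 0 when the pair set is empty (lag beyond the graph diameter).
    """
    if kind not in ("HATS", "H"):
        raise ValueError(f"kind must be 'HATS' or 'H', got {kind!r}")
    infl = influence_matrix(mol)
    w = atom_weights(mol, weight, table, heavy_only=False)
    D = mol.distance_matrix(heavy_only=False)
    iu, ju = np.triu_indices(mol.n_atoms, k=1)
    at_lag = D[iu, ju] == lag
    if not at_lag.any():
        return 0.0
    ii, jj = iu[at_lag], ju[at_lag]
    if kind == "HATS":
        h = infl.leverages
        return float(np.sum(w[ii] * h[ii] * w[jj] * h[jj]))
    hij = infl.H[ii, jj]
    pos = hij > 0
    return float(np.sum(w[ii[pos]] * w[jj[pos]] * hij[pos]))


def hgm(mol: Molecule, scale: float = 100.0) -> float:
    """Geometric mean of the atomic leverages, scaled by 100.

    HGM shrinks as molecules grow (each atom's share of the influence matrix
    trace falls), making it an inverse size measure.  An atom sitting exactly
    at the centroid has leverage 0 and makes the geometric mean undefined;
    that case is reported as an error naming the atom.
    """
    lev = influence_matrix(mol).leverages
    zero = np.nonzero(lev <= RANK_TOL)[0]
    if zero.size:
        raise MoleculeError(
            f"{mol.id}: atom {int(zero[0])} has zero leverage (at the centroid); "
            "geometric mean undefined"
        )
    return float(scale * np.exp(np.mean(np.log(lev))))


def whim_accessibility(
    mol: Molecule,
    axis: int,
    weight: str,
    table: AtomPropertyTable | None = None,
) -> float:
    """WHIM accessibility index E_m along principal axis m in {1, 2, 3}.

    Builds the weighted covariance of the coordinates centred at the
    weighted centroid, s_jk = sum_i w_i (q_ij - qbar_j)(q_ik - qbar_k) / sum_i w_i,
    takes its eigenvalues in decreasing order, projects the centred
    coordinates on eigenvector m to get scores t_im, and returns the inverse
    kurtosis E_m = lambda_m^2 * A / sum_i t_im^4.

    A degenerate axis (eigenvalue below tolerance, e.g. axis 2 of a linear
    chain) raises rather than returning 0.
    """
    if axis not in (1, 2, 3):
        raise ValueError("axis must be 1, 2 or 3")
    if mol.coords is None:
        raise MoleculeError(f"{mol.id}: WHIM requires 3D coordinates")
    w = atom_weights(mol, weight, table, heavy_only=False)
    centroid = (w[:, None] * mol.coords).sum(axis=0) / w.sum()
    Q = mol.coords - centroid
    S = (w[:, None] * Q).T @ Q / w.sum()
    eigval, eigvec = np.linalg.eigh(S)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    lam = eigval[axis - 1]
    if lam <= RANK_TOL * max(eigval[0], 1e-30):
        raise MoleculeError(
            f"{mol.id}: WHIM axis {axis} is degenerate (eigenvalue {lam:.3e})"
        )
    t = Q @ eigvec[:, axis - 1]
    return float(lam**2 * mol.n_atoms / np.sum(t**4))


def whim_eigenvalues(
    mol: Molecule, weight: str, table: AtomPropertyTable | None = None
) -> np.ndarray:
    """Weighted-covariance eigenvalues in decreasing order (for diagnostics)."""
    w = atom_weights(mol, weight, table, heavy_only=False)
    centroid = (w[:, None] * mol.coords).sum(axis=0) / w.sum()
    Q = mol.coords - centroid
    S = (w[:, None] * Q).T @ Q / w.sum()
    return np.sort(np.linalg.eigvalsh(S))[::-1]
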