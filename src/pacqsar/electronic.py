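"""Electronic descriptors: frontier orbital energies and chemical softness.

Orbital energies come from one of two paths: a user-supplied sidecar table
(the first-class path, for values computed at whatever quantum-chemical level
the user trusts) or a built-in extended-Hückel calculation on the embedded 3D
structure (a fast semiempirical estimate, clearly tagged as such so batch
output can flag predictions that rest on it).
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .chem_io import Molecule, MoleculeError, embed_3d, to_rdkit


class ElectronicError(ValueError):
    pass


@dataclass(frozen=True)
class OrbitalEnergies:
    """HOMO/LUMO energies in eV with provenance."""

    e_homo: float
    e_lumo: float
    source: str  # "user_supplied" or "semiempirical"

    def __post_init__(self):
        if not self.e_lumo > self.e_homo:
            raise ElectronicError(
                f"E_LUMO ({self.e_lumo}) must exceed E_HOMO ({self.e_homo})"
            )


def softness(orb: OrbitalEnergies, convention: str = "inverse_2eta") -> float:
    """Chemical softness from the HOMO–LUMO gap.

    Hardness eta = (E_LUMO - E_HOMO) / 2 (eV); the default convention returns
    sigma = 1 / (2 eta) in 1/eV.  The alternative ``inverse_eta`` convention
    (sigma = 1/eta) is offered because the softness definition in use varies
    across the QSAR literature.
    """
    eta = (orb.e_lumo - orb.e_homo) / 2.0
    if eta <= 0:
        raise ElectronicError(f"non-positive HOMO-LUMO gap (eta = {eta})")
    if convention == "inverse_2eta":
        return 1.0 / (2.0 * eta)
    if convention == "inverse_eta":
        return 1.0 / eta
    raise ValueError(f"unknown softness convention {convention!r}")


def read_sidecar(path: str | Path) -> pd.DataFrame:
    """Read a per-compound orbital-energy table (columns id, E_HOMO_eV, E_LUMO_eV)."""
    df = pd.read_csv(path, comment="#")
    required = {"id", "E_HOMO_eV", "E_LUMO_eV"}
    missing = required - set(df.columns)
    if missing:
        raise ElectronicError(f"sidecar {path} missing columns: {sorted(missing)}")
    return df.set_index(df["id"].astype(str))


def semiempirical_orbitals(mol: Molecule, seed: int = 7) -> OrbitalEnergies:
    """Extended-Hückel HOMO/LUMO (eV) on the (embedded if needed) 3D structure.

    Deterministic for a fixed geometry; when the molecule carries no
    coordinates it is embedded with the given seed first.
    """
    from rdkit.Chem import rdEHTTools  # deferred: optional heavy import

    work = mol if (mol.coords is not None and mol.explicit_h) else embed_3d(mol, seed)
    rdmol = to_rdkit(work)
    # the EHT engine drops scratch files (run.out, nul) into the cwd
    cwd = os.getcwd()
    with tempfile.TemporaryDirectory() as tmp:
        try:
            os.chdir(tmp)
            ok, res = rdEHTTools.RunMol(rdmol)
        finally:
            os.chdir(cwd)
    if not ok:
        raise ElectronicError(f"{mol.id}: extended-Hückel calculation failed")
    energies = res.GetOrbitalEnergies()
    n_occ = res.numElectrons // 2
    if n_occ < 1 or n_occ >= len(energies):
        raise ElectronicError(f"{mol.id}: cannot locate frontier orbitals")
    return OrbitalEnergies(
        e_homo=float(energies[n_occ - 1]),
        e_lumo=float(energies[n_occ]),
        source="semiempirical",
    )


def orbital_energies(
    mol: Molecule,
    sidecar: pd.DataFrame | None = None,
    seed: int = 7,
    require_user: bool = False,
) -> OrbitalEnergies:
    """Resolve HOMO/LUMO for a molecule: sidecar first, semiempirical fallback.

    Sidecar rows are keyed by molecule id.  ``require_user`` turns a missing
    sidecar entry into an error instead of falling back.
    """
    if sidecar is not None and mol.id in sidecar.index:
        row = sidecar.loc[mol.id]
        return OrbitalEnergies(
            e_homo=float(row["E_HOMO_eV"]),
            e_lumo=float(row["E_LUMO_eV"]),
            source="user_supplied",
        )
    if require_user:
        raise ElectronicError(
            f"{mol.id}: no sidecar orbital energies and user-supplied values required"
        )
    try:
        return semiempirical_orbitals(mol, seed)
    except MoleculeError as exc:
        raise ElectronicError(
            f"{mol.id}: no sidecar entry and semiempirical path failed: {exc}"
        ) from exc
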