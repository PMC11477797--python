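"""Molecule input/output, 3D embedding and per-atom property weights.

The :class:`Molecule` container is deliberately minimal — an element list, a
bond list and optional Cartesian coordinates — so that descriptor code can be
exercised on geometric toy structures (triangles, tetrahedra) that are not
chemically valid molecules.  Real chemistry (SMILES/SDF parsing, hydrogen
addition, distance-geometry embedding, force-field relaxation) is delegated to
RDKit and converted into this container at the boundary.

Graph conventions used throughout the package:

* 2D (graph) descriptors operate on the hydrogen-depleted graph; implicit and
  explicit hydrogen counts are tracked per atom so electrotopological states
  can still be computed.
* 3D descriptors operate on the hydrogen-included embedded structure.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from rdkit import Chem
from rdkit.Chem import AllChem

AROMATIC_ORDER = 1.5

#: principal quantum number of the valence shell, per element
_PRINCIPAL_QUANTUM = {
    "H": 1,
    "B": 2, "C": 2, "N": 2, "O": 2, "F": 2,
    "Si": 3, "P": 3, "S": 3, "Cl": 3,
    "Br": 4, "I": 5,
}

#: number of valence electrons, per element
_VALENCE_ELECTRONS = {
    "H": 1,
    "B": 3, "C": 4, "N": 5, "O": 6, "F": 7,
    "Si": 4, "P": 5, "S": 6, "Cl": 7,
    "Br": 7, "I": 7,
}


class MoleculeError(ValueError):
    """Raised for structurally invalid molecules or failed conversions."""


@dataclass(frozen=True)
class Molecule:
    """A molecular graph with optional 3D coordinates.

    Parameters
    ----------
    id : str
        Compound identifier carried through all tabular output.
    elements : tuple of str
        Element symbol per atom.
    bonds : tuple of (int, int, float)
        Bonded atom-index pairs with conventional bond order
        (1, 2, 3, or 1.5 for aromatic).
    coords : ndarray of shape (n_atoms, 3), optional
        Cartesian coordinates in Angstrom; either every atom has them
        or none do.
    implicit_h : tuple of int
        Implicit hydrogen count per atom (zero once hydrogens are explicit).
    explicit_h : bool
        True when hydrogen atoms are present as graph vertices.
    """

    id: str
    elements: tuple[str, ...]
    bonds: tuple[tuple[int, int, float], ...]
    coords: np.ndarray | None = None
    implicit_h: tuple[int, ...] = ()
    explicit_h: bool = False
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        n = len(self.elements)
        if not self.implicit_h:
            object.__setattr__(self, "implicit_h", (0,) * n)
        if len(self.implicit_h) != n:
            raise MoleculeError(f"{self.id}: implicit_h length mismatch")
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise MoleculeError(f"{self.id}: bond ({i},{j}) indexes a missing atom")
            if i == j:
                raise MoleculeError(f"{self.id}: self-bond on atom {i}")
        if self.coords is not None:
            c = np.asarray(self.coords, dtype=float)
            if c.shape != (n, 3):
                raise MoleculeError(
                    f"{self.id}: coordinates must cover every atom, got {c.shape}"
                )
            object.__setattr__(self, "coords", c)
        heavy = self.heavy_indices()
        if len(heavy) > 1 and self._n_heavy_components() > 1:
            raise MoleculeError(
                f"{self.id}: heavy-atom graph is disconnected "
                "(multi-fragment input; keep_largest_fragment may be used on read)"
            )

    # -- graph views -----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def heavy_indices(self) -> list[int]:
        return [i for i, el in enumerate(self.elements) if el != "H"]

    def adjacency(self, heavy_only: bool = True) -> np.ndarray:
        """Bond-order adjacency matrix over the selected atom set."""
        idx = self.heavy_indices() if heavy_only else list(range(self.n_atoms))
        pos = {a: k for k, a in enumerate(idx)}
        A = np.zeros((len(idx), len(idx)))
        for i, j, order in self.bonds:
            if i in pos and j in pos:
                A[pos[i], pos[j]] = A[pos[j], pos[i]] = order
        return A

    def distance_matrix(self, heavy_only: bool = True) -> np.ndarray:
        """Topological (shortest-path) distances; inf for disconnected pairs."""
        A = (self.adjacency(heavy_only) > 0).astype(float)
        if A.shape[0] == 1:
            return np.zeros((1, 1))
        return shortest_path(csr_matrix(A), method="D", unweighted=True)

    def heavy_degree(self) -> np.ndarray:
        """Heavy-atom degree of each heavy atom (hydrogen-depleted graph)."""
        return (self.adjacency(heavy_only=True) > 0).sum(axis=1)

    def total_h(self) -> np.ndarray:
        """Hydrogens attached to each heavy atom (implicit + explicit)."""
        heavy = self.heavy_indices()
        pos = {a: k for k, a in enumerate(heavy)}
        nh = np.array([self.implicit_h[a] for a in heavy], dtype=float)
        for i, j, _ in self.bonds:
            if self.elements[i] == "H" and j in pos:
                nh[pos[j]] += 1
            elif self.elements[j] == "H" and i in pos:
                nh[pos[i]] += 1
        return nh

    def contains(self, *symbols: str) -> bool:
        return any(el in symbols for el in self.elements)

    def _n_heavy_components(self) -> int:
        A = (self.adjacency(heavy_only=True) > 0).astype(int)
        return connected_components(csr_matrix(A), directed=False)[0]


# -- RDKit bridge --------------------------------------------------------


def _bond_order(bond: Chem.Bond) -> float:
    if bond.GetIsAromatic():
        return AROMATIC_ORDER
    return {Chem.BondType.SINGLE: 1.0,
            Chem.BondType.DOUBLE: 2.0,
            Chem.BondType.TRIPLE: 3.0}.get(bond.GetBondType(), 1.0)


def from_rdkit(mol: Chem.Mol, mol_id: str | None = None) -> Molecule:
    """Convert an RDKit molecule (already sanitized) to a :class:`Molecule`."""
    if mol_id is None:
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else "unnamed"
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _bond_order(b))
        for b in mol.GetBonds()
    )
    implicit_h = tuple(a.GetTotalNumHs(includeNeighbors=False) for a in mol.GetAtoms())
    coords = None
    if mol.GetNumConformers():
        coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
    explicit_h = any(el == "H" for el in elements)
    return Molecule(mol_id, elements, bonds, coords, implicit_h, explicit_h)


def to_rdkit(mol: Molecule) -> Chem.Mol:
    """Rebuild an RDKit molecule; only valid for chemically sensible graphs."""
    em = Chem.RWMol()
    for el in mol.elements:
        em.AddAtom(Chem.Atom(el))
    for i, j, order in mol.bonds:
        bt = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
              3.0: Chem.BondType.TRIPLE, AROMATIC_ORDER: Chem.BondType.AROMATIC}[order]
        em.AddBond(int(i), int(j), bt)
    m = em.GetMol()
    Chem.SanitizeMol(m)
    m.SetProp("_Name", mol.id)
    if mol.coords is not None:
        conf = Chem.Conformer(m.GetNumAtoms())
        for k, xyz in enumerate(mol.coords):
            conf.SetAtomPosition(k, tuple(float(c) for c in xyz))
        m.AddConformer(conf)
    return m


@dataclass
class ParseFailure:
    index: int
    record: str
    reason: str


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    return max(frags, key=lambda f: f.GetNumHeavyAtoms())


def read_molecules(
    path: str | Path,
    fmt: str = "smiles",
    strict: bool = False,
    keep_largest_fragment: bool = False,
) -> tuple[list[Molecule], list[ParseFailure]]:
    """Read molecules from a SMILES list or an SDF file.

    SMILES files hold one record per line, optionally ``SMILES<TAB>id``.
    Parse failures are collected per record (with the record index) and do
    not abort the batch unless ``strict`` is set.

    Returns
    -------
    (molecules, failures)

    Raises
    ------
    MoleculeError
        If the file is unreadable, yields zero valid records, or ``strict``
        is set and any record fails.
    """
    path = Path(path)
    if not path.exists():
        raise MoleculeError(f"no such file: {path}")
    mols: list[Molecule] = []
    failures: list[ParseFailure] = []

    def handle(idx: int, rdmol: Chem.Mol | None, record: str, mol_id: str):
        if rdmol is None:
            failures.append(ParseFailure(idx, record, "parse error"))
            return
        if len(Chem.GetMolFrags(rdmol)) > 1:
            if keep_largest_fragment:
                rdmol = _largest_fragment(rdmol)
            else:
                failures.append(ParseFailure(idx, record, "multi-fragment input"))
                return
        try:
            mols.append(from_rdkit(rdmol, mol_id))
        except MoleculeError as exc:
            failures.append(ParseFailure(idx, record, str(exc)))

    if fmt == "smiles":
        with open(path) as fh:
            for idx, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                smiles = parts[0]
                mol_id = parts[1] if len(parts) > 1 else f"mol{idx}"
                handle(idx, Chem.MolFromSmiles(smiles), smiles, mol_id)
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        for idx, rdmol in enumerate(supplier):
            name = None
            if rdmol is not None and rdmol.HasProp("_Name") and rdmol.GetProp("_Name"):
                name = rdmol.GetProp("_Name")
            handle(idx, rdmol, f"record {idx}", name or f"mol{idx}")
    else:
        raise MoleculeError(f"unknown format {fmt!r} (expected 'smiles' or 'sdf')")

    if strict and failures:
        raise MoleculeError(
            f"{path}: {len(failures)} record(s) failed under strict mode: "
            + "; ".join(f"#{f.index}: {f.reason}" for f in failures)
        )
    if not mols:
        raise MoleculeError(f"{path}: zero valid records")
    return mols, failures


def write_sdf(mols: Iterable[Molecule], path: str | Path) -> None:
    """Write molecules as SDF V2000 (3D block when coordinates are present)."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    for mol in mols:
        writer.write(to_rdkit(mol))
    writer.close()


def embed_3d(mol: Molecule, seed: int = 7, add_hs: bool = True) -> Molecule:
    """Seeded distance-geometry embedding followed by MMFF relaxation.

    Returns a copy with explicit hydrogens and 3D coordinates; the same
    (molecule, seed) pair always yields identical coordinates.  The seed is
    recorded in the returned molecule's ``meta`` for provenance.
    """
    rdmol = to_rdkit(replace(mol, coords=None))
    if add_hs:
        rdmol = Chem.AddHs(rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(rdmol, params) != 0:
        raise MoleculeError(f"{mol.id}: 3D embedding failed")
    try:
        AllChem.MMFFOptimizeMolecule(rdmol, maxIters=2000)
    except Exception:  # pragma: no cover - MMFF typing gaps on exotic atoms
        AllChem.UFFOptimizeMolecule(rdmol, maxIters=2000)
    out = from_rdkit(rdmol, mol.id)
    out.meta.update(mol.meta)
    out.meta["embed_seed"] = int(seed)
    return out


# -- atomic property weights --------------------------------------------


class AtomPropertyTable:
    """Carbon-scaled atomic property weights (m, p, e, v, i).

    Each scaled property equals exactly 1.0 for carbon; all entries are
    strictly positive.  Looking up an element absent from the table raises
    ``KeyError`` rather than silently defaulting.
    """

    PROPERTIES = ("m", "p", "e", "v", "i")

    def __init__(self, values: dict[str, dict[str, float]]):
        self._values = values
        carbon = values.get("C")
        if carbon is None:
            raise ValueError("property table must include carbon")
        for prop in self.PROPERTIES:
            if abs(carbon[prop] - 1.0) > 1e-12:
                raise ValueError(f"carbon-scaled property {prop!r} must be 1.0 for C")
        for el, props in values.items():
            for prop, val in props.items():
                if val <= 0:
                    raise ValueError(f"non-positive weight {prop}={val} for {el}")

    @classmethod
    def default(cls) -> "AtomPropertyTable":
        with resources.files("pacqsar.data").joinpath("atom_properties.csv").open() as fh:
            return cls._from_csv(fh)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AtomPropertyTable":
        with open(path) as fh:
            return cls._from_csv(fh)

    @classmethod
    def _from_csv(cls, fh) -> "AtomPropertyTable":
        rows = [r for r in csv.DictReader(l for l in fh if not l.startswith("#"))]
        values = {
            r["element"]: {p: float(r[p]) for p in cls.PROPERTIES} for r in rows
        }
        return cls(values)

    def lookup(self, element: str, prop: str) -> float:
        if prop not in self.PROPERTIES:
            raise KeyError(f"unknown property code {prop!r}")
        if element not in self._values:
            raise KeyError(f"element {element!r} not in atom property table")
        return self._values[element][prop]

    def elements(self) -> list[str]:
        return sorted(self._values)


def intrinsic_state(mol: Molecule) -> np.ndarray:
    """Kier–Hall intrinsic state I = ((2/L)^2 * dv + 1) / d per heavy atom.

    L is the principal quantum number of the valence shell, dv the valence
    electron count minus attached hydrogens, and d the heavy-atom degree on
    the hydrogen-depleted graph.
    """
    heavy = mol.heavy_indices()
    degree = mol.heavy_degree()
    n_h = mol.total_h()
    out = np.empty(len(heavy))
    for k, a in enumerate(heavy):
        el = mol.elements[a]
        if el not in _VALENCE_ELECTRONS:
            raise KeyError(f"no valence-electron count for element {el!r}")
        if degree[k] == 0:
            raise MoleculeError(
                f"{mol.id}: intrinsic state undefined for isolated heavy atom {a}"
            )
        L = _PRINCIPAL_QUANTUM[el]
        dv = _VALENCE_ELECTRONS[el] - n_h[k]
        out[k] = ((2.0 / L) ** 2 * dv + 1.0) / degree[k]
    return out


def atom_weights(
    mol: Molecule,
    weight: str,
    table: AtomPropertyTable | None = None,
    heavy_only: bool = False,
) -> np.ndarray:
    """Per-atom property weights aligned with atom order.

    ``weight`` is one of ``m p e v i s unit``.  ``unit`` returns all ones;
    ``s`` returns the Kier–Hall intrinsic state, which is defined on the
    hydrogen-depleted graph — explicit hydrogen atoms receive 0 in the
    full-length vector (they never enter graph descriptors).
    """
    if table is None:
        table = AtomPropertyTable.default()
    atoms = mol.heavy_indices() if heavy_only else list(range(mol.n_atoms))
    if weight == "unit":
        return np.ones(len(atoms))
    if weight == "s":
        istate = intrinsic_state(mol)
        heavy_pos = {a: k for k, a in enumerate(mol.heavy_indices())}
        return np.array(
            [istate[heavy_pos[a]] if a in heavy_pos else 0.0 for a in atoms]
        )
    return np.array([table.lookup(mol.elements[a], weight) for a in atoms])
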