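"""End-to-end descriptor computation for the activity models.

Glues the descriptor engines together: for each molecule computes exactly the
ten modeled descriptors — SpMin2Bh(m), SpMax8Bh(i), MATS5s, ATSC1e from the
hydrogen-depleted graph; HATS5p, H6e, HGM, E2v from the embedded 3D
structure; sigma and E_HOMO from the electronic layer — and records where
each value came from (computed here vs user-supplied).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .chem_io import AtomPropertyTable, Molecule, embed_3d
from .descriptors2d import AutocorrSpec, BurdenSpec, autocorrelation, burden_eigenvalue
from .descriptors3d import getaway_autocorrelation, hgm, whim_accessibility
from .electronic import OrbitalEnergies, orbital_energies, softness

#: descriptor names in canonical CSV-column order
MODEL_DESCRIPTORS = (
    "SpMin2Bh(m)",
    "SpMax8Bh(i)",
    "MATS5s",
    "ATSC1e",
    "HATS5p",
    "H6e",
    "HGM",
    "E2v",
    "sigma",
    "E_HOMO",
)


@dataclass
class DescriptorVector:
    """Named descriptor values with per-value provenance.

    ``provenance`` maps descriptor name to ``computed`` or ``user_supplied``;
    electronic descriptors obtained from the built-in semiempirical fallback
    are tagged ``computed(semiempirical)`` so downstream output can carry a
    warning flag.
    """

    mol_id: str
    values: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def keys(self):
        return self.values.keys()

    @property
    def semiempirical_electronics(self) -> bool:
        return any(p == "computed(semiempirical)" for p in self.provenance.values())


def compute_descriptors(
    mol: Molecule,
    table: AtomPropertyTable | None = None,
    sidecar: pd.DataFrame | None = None,
    seed: int = 7,
    require_user_electronics: bool = False,
) -> DescriptorVector:
    """All ten model descriptors for one molecule.

    Molecules without coordinates are embedded (seeded distance geometry +
    force-field relaxation) before the 3D block; the 2D block always uses the
    hydrogen-depleted graph of the input connectivity.
    """
    if table is None:
        table = AtomPropertyTable.default()
    vec = DescriptorVector(mol_id=mol.id)

    def put(name: str, value: float, source: str = "computed"):
        vec.values[name] = float(value)
        vec.provenance[name] = source

    put("SpMin2Bh(m)", burden_eigenvalue(mol, BurdenSpec("m", 2, "min"), table))
    put("SpMax8Bh(i)", burden_eigenvalue(mol, BurdenSpec("i", 8, "max"), table))
    put("MATS5s", autocorrelation(mol, AutocorrSpec("moran", 5, "s"), table))
    put("ATSC1e", autocorrelation(mol, AutocorrSpec("centred_broto_moreau", 1, "e"), table))

    mol3d = mol if (mol.coords is not None and mol.explicit_h) else embed_3d(mol, seed)
    put("HATS5p", getaway_autocorrelation(mol3d, "HATS", 5, "p", table))
    put("H6e", getaway_autocorrelation(mol3d, "H", 6, "e", table))
    put("HGM", hgm(mol3d))
    put("E2v", whim_accessibility(mol3d, 2, "v", table))

    orb = orbital_energies(mol3d, sidecar, seed, require_user=require_user_electronics)
    tag = "user_supplied" if orb.source == "user_supplied" else "computed(semiempirical)"
    put("E_HOMO", orb.e_homo, tag)
    put("sigma", softness(orb), tag)
    return vec


def descriptor_table(
    mols: list[Molecule],
    table: AtomPropertyTable | None = None,
    sidecar: pd.DataFrame | None = None,
    seed: int = 7,
    require_user_electronics: bool = False,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Descriptor DataFrame (index id, canonical column order) for a batch.

    Per-molecule failures are collected as (id, reason) and do not abort the
    batch; the caller decides whether an empty result is fatal.
    """
    rows, failures = [], []
    for mol in mols:
        try:
            vec = compute_descriptors(
                mol, table, sidecar, seed, require_user_electronics
            )
        except Exception as exc:
            failures.append((mol.id, str(exc)))
            continue
        row = {"id": mol.id, **{k: vec.values[k] for k in MODEL_DESCRIPTORS}}
        row["semiempirical_electronics"] = vec.semiempirical_electronics
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.set_index("id")
    return df, failures
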