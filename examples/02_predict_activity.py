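"""Score molecules with the built-in receptor-activity equations.

Non-halogenated compounds are routed to the log IEQ model (larger value =
lower receptor activity); Cl/Br compounds to the log %-TCDD-max model
(larger value = higher potency).
"""

from rdkit import Chem

from pacqsar import compute_descriptors, route_model
from pacqsar.chem_io import from_rdkit

for name, smiles in {
    "pyrene": "c1cc2ccc3cccc4ccc(c1)c2c34",
    "2-chloronaphthalene": "Clc1ccc2ccccc2c1",
}.items():
    mol = from_rdkit(Chem.MolFromSmiles(smiles), name)
    model = route_model(mol)
    vec = compute_descriptors(mol, seed=7)
    value = model.predict(vec.values)
    print(f"{name:>20s} -> {model.name}: {model.response} = {value:.2f}")

print(
    "\nPredictions made with semiempirical electronic descriptors; for "
    "production use,\nsupply HOMO/LUMO energies computed at a consistent "
    "quantum-chemical level."
)
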