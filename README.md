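# pacqsar

QSAR modeling of rat aryl hydrocarbon receptor (rAhR) activity for
polycyclic aromatic compounds (PACs): molecular descriptor computation,
application of the two published linear activity models, MLR model
(re)building with stepwise descriptor selection, the full validation
statistics suite, and leverage-based applicability-domain analysis.

**Who it is for.** Environmental toxicologists and cheminformaticians who
need to estimate the AhR-mediated potency of PAHs and their methylated,
oxygenated, nitrated, sulfur-containing or halogenated derivatives without
running a bioassay, and QSAR practitioners who want a transparent,
testable implementation of the descriptor and validation machinery behind
such models.

## The models

Two multiple-linear-regression equations predict the bioassay endpoints:

For 62 PACs without halogen substitution (endpoint: log IEQ, the induction
equivalent in the rat H4IIE luciferase assay; **larger log IEQ = lower
activity**):

```
log IEQ = 10.29·SpMin2Bh(m) − 9.03·HATS5p − 0.50·σ − 6.82·MATS5s
          − 5.58·H6e − 20.30·E2v + 2.43·SpMax8Bh(i) − 12.83
```

For 21 chlorinated/brominated PAHs (endpoint: log %-TCDD-max, the maximal
response as a percentage of the TCDD standard; **larger = more potent**):

```
log %-TCDD-max = −0.80·HGM − 33.75·E_HOMO + 31.71·ATSC1e − 3.34
```

The descriptors: `SpMin2Bh(m)` / `SpMax8Bh(i)` are extreme eigenvalues of
the Burden matrix weighted by atomic mass / ionization potential; `MATS5s`
and `ATSC1e` are Moran and centred Broto–Moreau 2D autocorrelations
(intrinsic-state and Sanderson-electronegativity weighted); `HATS5p`, `H6e`
and `HGM` are GETAWAY descriptors from the molecular influence matrix
H = M(MᵀM)⁺Mᵀ of centred 3D coordinates; `E2v` is the WHIM accessibility
index along the second principal axis; `σ = 1/(E_LUMO − E_HOMO)` is chemical
softness, and `E_HOMO` the frontier orbital energy in eV.

Model quality is assessed with R², Q², RMSE, BIAS, MAE and the extreme
errors MPE/MNE; external predictivity with Q²F1, Q²F2, Q²F3 and Lin's
concordance correlation coefficient; robustness by leave-one-out
cross-validation (Q²CV, RMSECV); and reliability of individual predictions
by the Williams plot (leverage vs standardized residual, warning threshold
h* = 3(p+1)/n, |SR| > 3).

## Worked example

```python
from rdkit import Chem
from pacqsar import compute_descriptors, route_model
from pacqsar.chem_io import from_rdkit

mol = from_rdkit(Chem.MolFromSmiles("c1cc2ccc3cccc4ccc(c1)c2c34"), "pyrene")
model = route_model(mol)          # no Cl/Br -> the log IEQ equation
vec = compute_descriptors(mol, seed=7)
print(model.response, "=", round(model.predict(vec.values), 2))
```

prints `log IEQ = -14.18`: pyrene's predicted induction equivalent on the
log scale — on the lower (more potent) side of the non-halogenated compound
range. Running `python examples/01_descriptors.py` shows the underlying
descriptor vector, e.g. for pyrene `SpMin2Bh(m) = 0.7010`,
`HATS5p = 0.4366`, `HGM = 9.2083`, with every electronic value tagged
`computed(semiempirical)` unless a sidecar CSV of HOMO/LUMO energies is
supplied.

A caution shown deliberately by `examples/02_predict_activity.py`: with the
built-in extended-Hückel fallback, E_HOMO is near −12 eV, far from the
quantum-chemical scale the halogenated-PAH equation was fitted on, so its
predictions (coefficient −33.75 per eV) are shifted by hundreds of log
units. For real use of that model, supply sidecar orbital energies computed
at a consistent QM level; batch output carries a
`semiempirical_electronics` flag for exactly this reason.

The same pipeline is available from the shell:

```sh
pacqsar descriptors --in mols.smi --out descriptors.csv --seed 7
pacqsar predict     --in mols.smi --out predictions.csv
pacqsar validate    --data dataset.csv --split-fraction 0.7 --seed 1 --out report.csv
pacqsar ad          --train dataset.csv --out ad.csv --plot williams.svg
pacqsar fixtures    --out-dir fixtures/
```

`examples/03_build_and_validate.py` rebuilds an MLR model on a synthetic
62-compound dataset and prints the familiar summary table (R² = Q² on
in-sample fits — an OLS identity — and their divergence on the test set);
`examples/04_applicability_domain.py` prints h* = 0.387 for the
62-compound/7-descriptor design and writes the Williams plot.

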