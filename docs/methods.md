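# Methods

This note records the scientific and numerical choices behind `pacqsar`:
what each component computes, the conventions adopted where the field has
more than one, and what the synthetic fixtures do and do not establish.

## Molecular representation

A molecule is an element list, a bond list with conventional orders
(1, 2, 3, aromatic = 1.5) and optional Cartesian coordinates. Aromatic
bonds keep the 1.5 order rather than a Kekulé assignment so that all graph
descriptors are invariant under atom renumbering and kekulization choices.
Multi-fragment inputs are rejected by default (a descriptor of a salt or
mixture is ambiguous); a flag keeps the largest fragment instead. Graph
descriptors (Burden eigenvalues, 2D autocorrelations) use the
hydrogen-depleted graph; geometric descriptors (GETAWAY, WHIM) use the
hydrogen-included embedded structure. This split follows the dominant
convention of the commercial descriptor engines these descriptor names come
from; it is stated explicitly so deviations are diagnosable.

3D coordinates come from seeded ETKDG distance-geometry embedding followed
by MMFF force-field relaxation. The level of theory behind the original
models' geometries is not public; a force-field geometry is adequate for
the leverage-based GETAWAY/WHIM descriptors of rigid fused-ring systems,
but exact numeric parity with any particular descriptor engine is not
promised. The embedding seed is recorded in the molecule metadata and in
every output file.

## Atomic property weights

Descriptor weights (atomic mass m, polarizability p, Sanderson
electronegativity e, van der Waals volume v, ionization potential i) are
carbon-scaled (carbon ≡ 1) and shipped as an editable CSV
(`src/pacqsar/data/atom_properties.csv`), taken from the standard
molecular-descriptor handbook tables. Shipping the table as data rather
than constants makes parity with other engines auditable and
recalibratable. Lookup of an element missing from the table is an error —
silently defaulting a weight would corrupt descriptors undetectably. The
intrinsic state (weight code `s`) is the Kier–Hall electrotopological
quantity I = ((2/L)²·δᵛ + 1)/δ on the hydrogen-depleted graph (L the
valence-shell principal quantum number, δᵛ valence electrons minus attached
hydrogens, δ the heavy-atom degree).

## Burden eigenvalues

The Burden matrix carries atomic weights on the diagonal; bonded pairs get
0.1 × bond order, plus 0.01 for **each** bonded atom of degree 1 (so a
two-atom molecule has off-diagonal 0.12 and eigenvalues w ± 0.12); all
remaining off-diagonal entries are 0.001. These constants follow the
classical formulation and live in a config object (`BurdenConfig`) because
the commercial "Bh" variants are not publicly documented bit-for-bit.
`SpMinkBh(w)`/`SpMaxkBh(w)` are the k-th smallest/largest eigenvalues.

## 2D autocorrelations

With centred weights c_i = w_i − w̄ over the A heavy atoms and the pair set
P_k of atom pairs (i < j, counted once) at topological distance k:
ATSC_k = Σ c_i c_j (centred Broto–Moreau) and
MATS_k = (Σ c_i c_j / |P_k|) / (Σ c_i² / A) (Moran). Empty pair sets give
0; constant weights give Moran 0 (the 0/0 convention). Counting pairs once
is the standard definition; doubling would be a pure scale change.

## GETAWAY and WHIM

The molecular influence matrix is H = M(MᵀM)⁺Mᵀ of coordinates centred at
the unweighted centroid, built from the SVD with singular values below
1e−8 of the maximum treated as zero. Fused-ring aromatics are essentially
planar, so the rank-2 case is the *common* path, not an edge case; the
leverages always sum to the coordinate rank (3 general, 2 planar, 1
linear). HATS_k(w) = Σ (w_i h_i)(w_j h_j) and H_k(w) = Σ w_i w_j h_ij (over
pairs at topological distance k; H_k restricted to h_ij > 0).
HGM = 100·(∏ h_i)^(1/A) is the geometric mean of the leverages — an inverse
size measure; an atom exactly at the centroid (leverage 0) makes it
undefined and is reported as an error naming the atom. The WHIM
accessibility E_m is the inverse kurtosis λ_m²·A/Σt⁴ of the atomic scores t
along principal axis m of the weighted covariance (weighted centroid,
weights normalized by their sum). A degenerate axis raises rather than
returning 0, since 0 is a legitimate descriptor value. The ×100 HGM scale
and inverse-kurtosis E_m follow the standard handbook conventions (the
model equations reference these descriptors by name only).

## Electronic descriptors

Softness is σ = 1/(2η) with hardness η = (E_LUMO − E_HOMO)/2 in eV, i.e.
σ = 1/gap; the alternative 1/η convention is selectable because usage
varies across the QSAR literature. Orbital energies come from a sidecar CSV
(`id,E_HOMO_eV,E_LUMO_eV`) when provided — the first-class path — or from
RDKit's bundled extended-Hückel engine on the embedded structure.
Extended-Hückel orbital energies sit on a systematically deeper scale
(benzene HOMO ≈ −12.8 eV) than the DFT-class values regression models are
typically trained on; every descriptor vector therefore records provenance,
and batch predictions made with fallback electronics carry a
`semiempirical_electronics` warning flag. For the halogenated-PAH equation,
whose E_HOMO coefficient is −33.75 per eV, using fallback electronics
shifts predictions by hundreds of log units — the flag is not cosmetic.

## Built-in models and routing

The two published equations ship as packaged JSON with coefficients exactly
as printed (two decimals); they are never re-derived. Prediction is
intercept + Σ coef·value with a *missing descriptor an error, never
imputed*. Batch scoring routes Cl/Br-containing compounds to the
log %-TCDD-max model and all others to the log IEQ model, mirroring the
datasets the two models were built on; the route is overridable per run.
The package reports the modeled response and its direction (larger log IEQ
= lower activity; larger log %-TCDD-max = higher potency) but computes no
cross-endpoint potency ranking.

## Model building

OLS is solved by least squares on the intercept-augmented design; a
rank-deficient design raises with the collinear columns named (pivoted QR).
Descriptor selection is forward stepwise by partial F-test (entry threshold
α = 0.05, default cap at the requested number of terms, lexicographic
tie-break), which makes the procedure deterministic. The original models
were built with a commercial stepwise-MLR tool whose exact settings are
unpublished; forward stepwise with an F-to-enter is the textbook
counterpart and is documented and swappable. Train/test splitting uses
|train| = round(fraction·n) — reproducing the published 43/19 and 15/6
splits at fraction 0.70 — with either a seeded random assignment or a
ranked-response stride (every k-th compound by sorted response into the
test set), both offered because the original assignment rule is unstated.

## Validation statistics

Residuals are e = observed − predicted everywhere. R² is the squared
Pearson correlation of observed vs predicted; Q² = 1 − SSE/SST. The two
coincide on in-sample OLS fits (checked as a property test) and diverge on
external data — the pair of definitions consistent with the published
tables, which print identical training R²/Q² but different test-set values.
MPE/MNE are the extreme positive/negative residuals (the printed MPE values
exceed the corresponding RMSE severalfold, which is only consistent with
extremes, not means); a mean-of-signs variant is config-selectable.
External metrics: Q²F1 (test deviations referenced to the training mean),
Q²F2 (to the test mean), Q²F3 (mean squared error against training
variance), and Lin's CCC with 1/n moments. Leave-one-out uses the
hat-matrix shortcut e/(1 − h), verified in tests against n explicit refits
to 1e−10; Q²CV = 1 − PRESS/SST, RMSECV = √(PRESS/n).

## Applicability domain

Leverage h = x̃ᵀ(X̃ᵀX̃)⁻¹x̃ with the intercept included; the warning threshold
is h* = 3(p+1)/n (0.39 for the 62-compound/7-descriptor design, 0.57 for
21/3). Standardized residuals are internally studentized,
SR = e/(s√(1 − h)) with s² = SSE/(n − p − 1); the raw e/s variant is
selectable since the original definition is unstated. Compounds classify
exhaustively as in-domain, structural outlier (h > h*), response outlier
(|SR| > 3) or both. On an essentially exact fit (s below 1e−10 of the
response scale) all SR are defined as 0 rather than a 0/0 ratio. A query
point with h = 1 (exact interpolation) has undefined SR and is reported as
such.

## Synthetic fixtures

The geometric toys (two-atom chain, four-atom path, equilateral triangle,
regular tetrahedron, a planar pentagon in one test) have closed-form
descriptors used as frozen expected values: triangle leverages 2/3,
tetrahedron 3/4 and HGM 75, two-atom Burden eigenvalues w ± 0.12, four-path
ATSC₁ = 1.25 and MATS₁ = 1/3 under weights (1,2,3,4), planar four-point
WHIM E₂ = 0.5. Their coordinates are hardcoded rather than re-embedded so
the expected values cannot drift with an embedding library version; the
`fixtures` CLI subcommand emits them as SDF/CSV in the same dialects the
real pipeline consumes. A useful geometric fact surfaced by testing: any
four-point rank-3 configuration has all leverages exactly 3/4 (H is then
the centred projector I − J/4), so leverage-vs-geometry behaviour must be
probed with n > rank + 1 points.

Synthetic regression datasets are X ~ iid N(0,1), y = intercept + Xβ +
N(0, σ²). The two study-shaped generators (62×7 and 21×3) keep the
direction of the published coefficient vectors but rescale them, and set
σ, so the *population* fit statistics match the published summaries
(Q² ≈ 0.80 / RMSE ≈ 0.53 and Q² ≈ 0.89 / RMSE ≈ 0.21): Var(signal) =
RMSE²·Q²/(1 − Q²). Individual replicates scatter around those targets —
at n = 21 especially, a single seed can sit several hundredths away.
What passing tests on these fixtures shows: the estimators, statistics and
domain analysis are implemented correctly under the stated model. What they
do not show: that descriptor values numerically match the original
commercial engine on real PACs (weights, Burden constants and GETAWAY/WHIM
scalings are exposed in config precisely so such parity can be audited if
the original per-compound table is available; the acceptance tests include
golden checks that activate when a copy is placed under `tests/data/`),
nor that standard-normal descriptor space resembles real PAC descriptor
space, which is strongly correlated and bounded.

## Problem sizes and determinism

Property tests run on graphs of up to ~13 atoms, 50–100 random
designs/rotations per invariant, and the two study-sized synthetic
datasets; the full suite completes in a few seconds. Every stochastic
component (embedding, data generation, splitting) is seeded, and all CLI
output embeds the package version, a configuration hash and the seed.

## Known limitations

* Descriptor parity with the original engine's per-compound values is
  unverified (their geometry protocol and engine version are unpublished).
* The extended-Hückel electronic fallback is a scale-shifted estimate, fit
  only for qualitative ordering; quantitative use of the halogenated-PAH
  model requires user-supplied orbital energies.
* No uncertainty intervals on predictions (the source models provide none),
  no conformer ensembles, no tautomer handling, and no regularized or
  nonlinear model building.
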