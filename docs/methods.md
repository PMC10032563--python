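# Methods

This note documents the models implemented in `taur2`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices a user should know before trusting
a number.

## Units and conventions

All computation is in Å, kcal/mol, elementary charges and ps. Radius
of gyration, end-to-end distance and SASA are converted to nm / nm²
only in reporting containers (`EnsembleSeries`, TSV tables), matching
the conventional reporting units for peptide ensembles. Atom indices
are 0-based throughout; PDB serial numbers are presentation only.
Constants: k_e = 332.0637 kcal·Å/(mol·e²), k_B = 0.0019872
kcal/(mol·K), T = 310 K by default (the simulation temperature of the
study this pipeline supports).

## End-point binding free energy

ΔG_bind = ΔE_int + ΔE_vdw + ΔE_eel + ΔG_p^sol + ΔG_np^sol − TΔS,
with every Δ-term evaluated as value(complex) − value(receptor) −
value(ligand) on coordinates extracted from the *same* complex frame
(single-trajectory protocol). Consequences exploited by the code:

* ΔE_int cancels identically and is never computed; bonded topology
  sections are not even parsed.
* ΔE_vdw and ΔE_eel reduce exactly to the intergroup pair sums, which
  is how `mmgbsa_frame` computes them (verified against the
  three-way-difference definition in the tests).

No nonbonded cutoff is applied: cutoffs belong to the MD engine, not
to end-point re-evaluation. Lennard-Jones uses Lorentz–Berthelot
combination on (rmin/2, ε); Coulomb uses k_e q_i q_j / r.

### Polar solvation (generalized Born)

Effective Born radii come from Hawkins–Cramer–Truhlar pairwise
descreening with the Onufriev–Bashford–Case tanh rescaling; the
default (α, β, γ) = (1.0, 0.8, 4.85) is the OBC-II parameter set, with
ε_in = 1, ε_out = 78.5. The energy is the usual Still-form double sum
with f_GB = √(r² + R_iR_j·exp(−r²/(4R_iR_j))), self terms included
(f_GB = R_i).

Two deliberate choices:

* **Dielectric offset defaults to 0 Å** (AMBER uses 0.09). With a zero
  offset a lone ion's effective radius equals its intrinsic radius and
  the Born closed form is reproduced exactly, which makes the model
  analytically checkable; the offset is a config field
  (`GBConfig.offset`) for users who want AMBER-compatible radii.
* **No salt screening by default.** The analysis layer models the
  solvent only through the dielectric; an optional Debye–Hückel factor
  (`GBConfig.kappa`, 1/Å) multiplies the exterior term when set.

Which GB flavor (and radii set) produced any particular published
table is generally under-determined from a methods section; absolute
polar-solvation numbers should therefore be compared across variants
computed *with the same settings*, which the config object makes
reproducible.

### Surface area

Default algorithm is the LCPO linear combination of pairwise overlaps,
A_i = P1·S1 + P2·ΣA_ij + P3·ΣA_jk + P4·Σ(A_ij·ΣA_jk), with probe
radius 1.4 Å and per-atom radii defaulting to the LJ rmin/2 (config
overridable). **The weight table shipped here is this package's own
calibration of the LCPO form**: the published weights are keyed on
bonded-neighbor classes, but these topologies carry no bond table, so
rows are keyed on the geometric overlapping-neighbor count (clamped to
6) and were fit per element against a Shrake–Rupley reference (960
points/atom) on nonbonded sphere packs, sphere pairs and caged
configurations. Behaviour guaranteed by construction and enforced in
tests: an atom with no overlapping neighbor is an exact
solvent-expanded sphere; per-atom areas are clamped to [0, 4πR²], so
the total never exceeds the free-sphere sum; totals agree with an
independent point-sampling oracle to within 10% on random packs.
A deterministic golden-spiral Shrake–Rupley implementation is
available as `sasa.algorithm = "shrake_rupley"` for cross-checks.
Hydrogens carry zero LCPO weight (the AMBER convention) and can be
excluded entirely via `SasaConfig.include_hydrogens`.

The nonpolar solvation term is γ·SASA + β with γ = 0.0072 kcal/mol/Å²
and β = 0 by default.

### Entropy

* **WSAS**: per frame, TS(X) = c0 + Σ w(element)·area_atom for complex,
  receptor and ligand from the same frame; TΔS is the frame average of
  the difference. The fitted per-atom-type weights of the published
  WSAS parameterization are not redistributable here, so the shipped
  per-element defaults are order-of-magnitude placeholders meant to
  keep the pipeline runnable; any quantitative use should supply its
  own weights (every test does, so no test result depends on the
  defaults).
* **Interaction entropy**: TΔS = −k_BT·ln⟨exp(β(E_t − ⟨E⟩))⟩ over the
  per-frame interaction-energy series, computed with log-sum-exp so
  fluctuations of 100 kcal/mol cannot overflow. The series defaults to
  the gas-phase ΔE_vdw + ΔE_eel (the workflow's `entropy_method="ie"`);
  whether a published IE used gas-phase or total interaction energy is
  usually unstated, so the choice is explicit here and the function
  accepts any series. Note the estimator is an exponential average:
  for βσ ≳ 3 it is heavy-tailed and slow to converge, which is why the
  acceptance script reports a median over independent series.

### Aggregation and decomposition

Replica averaging discards the first 25% of each replica's frames by
default (mirroring the common "last N ns of each run" convention),
averages within replicas, and reports mean-of-replica-means with the
*sample standard deviation of replica means* as the spread — published
"±" values rarely state their definition, so this one is fixed and
documented. ΔG_bind is assembled from the component means exactly
(additivity is an invariant, tested at 1e-9).

Per-residue decomposition attributes to each ligand residue its
pairwise LJ + Coulomb terms with the receptor, the full GB cross-term
(ligand-side attribution — profiles are shown for ligand residues
only; a half-half split would halve every bar without changing shape),
and γ times the residue's SASA change on binding. The pairwise-additive
parts sum to the intergroup totals by construction (tested at 1e-6).
Residue distance is the time-averaged minimum any-atom distance; RMSF
is computed after least-squares (Kabsch/SVD) superposition on the
receptor, on each residue's representative atom (Cα when present, else
first heavy atom).

## Ensemble observables

Rg is mass-weighted; e2e uses the terminal residues' Cα atoms
(capping groups, which have no Cα, are naturally excluded); RMSD is
least-squares-fit over the analysis group.

Secondary structure uses the Kabsch–Sander electrostatic hydrogen-bond
criterion (27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol,
amide H rebuilt 1 Å from N along the preceding C=O direction; chain
breaks detected by a C(i−1)–N(i) distance > 2.5 Å). Turn hydrogen
bonds i→i+3/i+4/i+5 mark the spanned residues helix (3-10, α and π
all count as "helix"); Kabsch–Sander parallel/antiparallel bridge
patterns mark β; helix takes priority; everything else — including
residues with missing backbone atoms, which are reported with a
warning — is coil. This is a documented approximation: it is *not* the
STRIDE program (whose torsion-propensity terms are not public in
tabular form), so absolute secondary-structure contents from
STRIDE-based analyses are comparable only qualitatively.

Contact maps: a ligand residue–receptor residue pair is in contact in
a frame iff the minimum distance over all atom pairs (hydrogens
included by default; `heavy_atoms_only` available) is ≤ 0.3 nm;
occupancy is the contact-frame fraction. Occupancy is monotone in the
cutoff (tested).

## Free-energy landscape and clusters

ΔG(bin) = −k_BT·[ln P(bin) − ln P_max] on a 2-D histogram over
(e2e, Rg); the global minimum is exactly 0 and empty bins are NaN
(undefined), never 0. Default 50×50 bins — fine enough to resolve the
two-basin synthetic landscapes at the frame counts used here; the
advisory local-minima counter (`suggest_k`) should be run on a coarser
grid (20–30 bins for a few thousand frames) because sparse high-ΔG
bins read as spurious minima. k is always a user decision.

Clustering is k-means (scikit-learn: k-means++ seeding from the given
seed, best of 10 restarts) on per-axis z-scored coordinates — e2e and
Rg have different dynamic ranges, and clustering the raw plane would
weight e2e ~3×. Populations are cluster-size fractions; each cluster's
representative frame is its member closest (normalized Euclidean) to
the center, ties to the smallest frame index.

## Synthetic data: what it does and does not show

The generators produce ensembles with *known statistical structure*,
not physics:

* `build_toy_complex` — receptor on a jittered 4 Å lattice, ligand
  beads serpentining 4 Å above the top face (3–5.5 Å from the
  surface); plausible per-element parameters (|q| ≤ 1 e after
  per-group neutralization, Born radii 1.5–1.8 Å); partition pre-set.
  Per-group neutralization makes all interaction terms vanish on
  separation, giving the pipeline a clean non-interacting limit.
* `sample_harmonic_ensemble` — i.i.d. Gaussian positional fluctuation
  of stated σ about the pose, frames 10 ps apart; no dynamics, no
  correlations.
* `sample_two_state_chain` — per frame, a basin is drawn by weight, a
  per-frame (e2e, Rg) target = basin center + Gaussian noise is
  matched by solving a two-parameter regular-helix family (turn angle,
  rise; bond 3.8 Å, 16 beads by default), and the chain gets a random
  rigid orientation. Default basins (1.0 nm, 0.9 nm) and (2.5 nm,
  1.2 nm) sit in the region where disordered-peptide landscape minima
  are typically found; default weights 0.8/0.2.
* `build_ideal_backbone` — N/Cα/C/O at standard bond lengths/angles
  and uniform (φ, ψ), ω = 180°; `build_antiparallel_sheet` pairs a
  (−139°, 135°) strand with its two-fold copy, placed by a
  deterministic grid search maximizing inter-strand hydrogen bonds.

Every generator is a pure function of (parameters, seed).

Passing tests on these ensembles demonstrates that the *estimators*
are correct (they recover known mixture weights, closed-form entropies,
exact geometric areas, generative basin positions). They do not
demonstrate force-field accuracy, sampling convergence of real
trajectories, or solvent effects — none of which are claims this
package makes.

## Numerical choices and degenerate inputs

* Atoms closer than 1e-6 Å are an error in pair energies (singular
  Coulomb), as are non-positive effective Born radii (naming the atom).
* Interaction entropy requires ≥ 2 frames; RMSF ≥ 2 frames and a
  non-degenerate (≥ 3 atoms, non-colinear) fit group.
* Histogramming a constant series is valid (numpy's auto range): a
  single-conformation ensemble yields one occupied bin at ΔG = 0.
  An explicitly zero-width axis range is an error.
* k-means requires k ≤ number of distinct points; with k = n distinct
  points the inertia is 0.
* TSV output uses a fixed float format and line terminator, so
  identical configs and seeds produce byte-identical files (tested).

## Problem sizes

The shipped studies use 125 + 10-atom complexes with 30–50 frames,
2000-frame monomer ensembles (10 000 in the acceptance script's
recovery check), and 2×10⁵-sample entropy series — sizes chosen so the
whole suite exercises every code path with tight statistical
tolerances while remaining a desk-scale computation.

## Known limitations

* GB flavor, radii set and γ/β conventions differ across MM-GBSA
  implementations; absolute solvation numbers are comparable only
  within one convention.
* The LCPO weight table is calibrated for nonbonded sphere packs (see
  above); for bonded all-atom molecules the published bonded-class
  weights would be preferable if a bond table were available.
* The secondary-structure assignment approximates STRIDE by
  Kabsch–Sander hydrogen bonding; contents agree qualitatively, not
  numerically.
* Interaction entropy inherits the exponential average's slow
  convergence for large fluctuations.
* No explicit-solvent observables (e.g. hydration-layer statistics)
  are computable from these inputs.
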