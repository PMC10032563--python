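# taur2 — end-point binding energetics and ensemble analysis for the tau R2 repeat

Serine phosphorylation of tau's second microtubule-binding repeat (R2,
containing the aggregation-prone hexapeptide PHF6\* = VQIINK) weakens
tau's grip on microtubules and disorders the free peptide — a molecular
step on the road to tangle formation in tauopathies. This package
implements the complete *post-simulation analysis layer* for that kind
of study: given a topology with nonbonded parameters and an ensemble of
complex or monomer conformations, it computes

* **MM-GBSA binding free energies** by the single-trajectory, end-point
  route

  ΔG_bind = ΔE_int + ΔE_vdw + ΔE_eel + ΔG_p^sol + ΔG_np^sol − TΔS

  with ΔE_int ≡ 0 (single-trajectory cancellation), generalized-Born
  polar solvation (Hawkins–Cramer–Truhlar descreening with OBC-II
  rescaling), an LCPO-form surface-area term, and **two entropy
  estimators**: weighted-SASA (WSAS) conformational entropy and the
  interaction entropy TΔS = −k_BT·ln⟨exp(βΔE_int)⟩;
* **per-residue decomposition** of the binding energy plus
  residue–microtubule distances and RMSF profiles;
* **residue–residue contact maps** at a 0.3 nm minimum-distance cutoff;
* **ensemble observables** for the free monomer: radius of gyration,
  end-to-end distance, SASA, RMSD, and a hydrogen-bond-pattern
  (Kabsch–Sander energetics) secondary-structure assignment mapped to
  the three families helix / β / coil;
* **free-energy landscapes** ΔG = −k_BT·[ln P − ln P_max] over
  (end-to-end, Rg) with k-means clustering, cluster populations and
  representative structures.

Because the underlying multi-hundred-nanosecond explicit-solvent
trajectories of a ~70k-water tubulin system are not reproducible at
desk scale, a first-class `synthetic` module generates every input the
pipeline needs with *known* ground truth: bound toy complexes with
harmonic fluctuations, two-basin bead-chain ensembles with prescribed
mixture weights in (e2e, Rg) space, ideal helical / extended /
paired-strand backbones, and Gaussian interaction-energy series.

## Worked example

The numbered drivers under `analysis/` run the two studies end to end
on synthetic data (`01` writes the systems; `02` and `03` analyse
them):

```bash
python analysis/01_build_systems.py
python analysis/02_binding_energy.py
python analysis/03_monomer_ensemble.py
```

`02_binding_energy.py` first assembles the published MM-GBSA component
means for the four R2 systems into binding free energies (kcal/mol):

```
            system  dg_bind_wsas  dg_bind_ie
             R2-WT         -39.9       -53.6
        R2-pSer289          -8.7       -21.9
        R2-pSer293         -12.3       -28.0
R2-pSer289+pSer293          -1.5       -19.0
-> binding weakens monotonically with phosphorylation under both entropy routes
```

i.e. every phosphorylation weakens R2–microtubule binding, and the
doubly phosphorylated peptide barely binds at all — under either
entropy estimator. It then runs the full per-frame pipeline on the
synthetic complex and writes the component table, time course,
per-residue decomposition and contact map under `results/binding/`.

`03_monomer_ensemble.py` analyses a 2000-frame two-basin chain ensemble
(generative weights 0.8/0.2):

```
2000 frames: Rg 0.96 nm, e2e 1.30 nm, SASA 13.1 nm^2
cluster populations [0.798 0.202] (generative truth [0.798 0.202])
  cluster 0: pop 0.798 at e2e 1.00 nm, Rg 0.90 nm
  cluster 1: pop 0.202 at e2e 2.49 nm, Rg 1.20 nm
basin free-energy gap from populations: 0.848 kcal/mol (kBT ln 4 = 0.854)
suggested cluster count from FEL minima (20-bin grid): 2
```

The clustering recovers the generative mixture to three decimals, and
the basin free-energy gap read off the landscape matches the
closed-form k_BT·ln 4 at 310 K.

## Layout

```
src/taur2/       library: topology/prmtop/pdb I/O, energetics, sasa,
                 entropy, binding, ensemble, fel, synthetic, workflow
analysis/        numbered study drivers (write under results/)
tests/           pytest suite (unit, property and acceptance tests)
scripts/         acceptance.py
docs/methods.md  models, parameters, numerical choices, limitations
```
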