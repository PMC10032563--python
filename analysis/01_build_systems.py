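#!/usr/bin/env python
"""Build the synthetic study systems and write them to disk.

Produces, under results/synthetic/:
  * complex.prmtop / complex.pdb — a bound peptide–receptor toy
    complex (125 receptor atoms, 10 ligand beads) with 50 harmonic
    fluctuation frames (sigma = 0.3 A), standing in for the
    R2–microtubule complex trajectories;
  * monomer.pdb — a 2000-frame two-basin bead-chain ensemble
    (weights 0.8/0.2 over a compact and an extended state), standing
    in for the monomeric R2 ensembles;
  * helix.pdb / extended.pdb — ideal backbones used by the
    secondary-structure checks.

Everything is deterministic for the seed printed below.
"""

from pathlib import Path

import numpy as np

import taur2 as t

SEED = 2026
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    spec = t.ToySpec(n_receptor_atoms=125, n_ligand_atoms=10,
                     jitter_sigma=0.3, n_frames=50, seed=SEED)
    top, pose = t.build_toy_complex(spec)
    traj = t.sample_harmonic_ensemble(top, pose, spec.jitter_sigma,
                                      spec.n_frames, seed=SEED)
    t.write_prmtop_subset(top, OUT / "complex.prmtop")
    t.write_multimodel_pdb(traj, OUT / "complex.pdb")
    t.write_topology_yaml(top, OUT / "complex.yaml")
    print(f"complex: {top.n_atoms} atoms, {top.n_residues} residues, "
          f"{traj.n_frames} frames -> {OUT / 'complex.pdb'}")

    chain, labels = t.sample_two_state_chain(
        weights=(0.8, 0.2), n_frames=2000, seed=SEED
    )
    t.write_multimodel_pdb(chain, OUT / "monomer.pdb")
    t.write_prmtop_subset(chain.topology, OUT / "monomer.prmtop")
    np.savetxt(OUT / "monomer_basin_labels.tsv", labels, fmt="%d",
               header="basin", comments="")
    print(f"monomer: {chain.n_frames} frames, basin occupancy "
          f"{np.mean(labels == 0):.3f}/{np.mean(labels == 1):.3f} "
          f"(target 0.8/0.2)")

    for name, (phi, psi) in (("helix", (-57.0, -47.0)),
                             ("extended", (-180.0, 180.0))):
        bb_top, xyz = t.build_ideal_backbone(15, phi, psi)
        bb = t.Trajectory(xyz[None], [0.0], bb_top)
        t.write_multimodel_pdb(bb, OUT / f"{name}.pdb")
    print(f"ideal backbones -> {OUT / 'helix.pdb'}, {OUT / 'extended.pdb'}")


if __name__ == "__main__":
    main()
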