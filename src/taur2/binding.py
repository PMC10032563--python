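"""MM-GBSA binding free energy: per-frame Δ-terms, replica averaging,
per-residue decomposition and RMSF.

The single-trajectory protocol extracts receptor and ligand
coordinates from the complex frames, so the internal-energy change
cancels exactly and ΔE_vdw/ΔE_eel reduce to the intergroup pair sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .energetics import (
    EnergeticsError,
    FrameEnergies,
    GBConfig,
    gb_effective_radii,
    gb_polar_energy,
    lj_coulomb_interaction,
    nonpolar_energy,
)
from .constants import COULOMB_CONSTANT, DEFAULT_NP_BETA, DEFAULT_NP_GAMMA
from .entropy import EntropyTerm
from .sasa import SasaConfig, sasa
from .topology import Topology, Trajectory


class MeanSpread(NamedTuple):
    mean: float
    spread: float


@dataclass(frozen=True)
class BindingEnergyComponents:
    """Averaged MM-GBSA components, kcal/mol (mean, spread)."""

    de_vdw: MeanSpread
    de_eel: MeanSpread
    dg_polar: MeanSpread
    dg_nonpolar: MeanSpread
    t_delta_s: MeanSpread
    dg_bind: MeanSpread
    n_replicas: int
    frames_used: tuple[int, int]   # (first retained frame, n per replica)

    @property
    def enthalpy(self) -> float:
        """MM-GBSA mean without the entropy term."""
        return (self.de_vdw.mean + self.de_eel.mean + self.dg_polar.mean
                + self.dg_nonpolar.mean)


@dataclass(frozen=True)
class ResidueContribution:
    residue_index: int
    energy: float              # kcal/mol
    mean_min_distance: float   # Å
    e_vdw: float = 0.0
    e_eel: float = 0.0
    e_polar: float = 0.0
    e_nonpolar: float = 0.0


def mmgbsa_frame(top: Topology, frame: np.ndarray,
                 gb_config: GBConfig = GBConfig(),
                 sasa_config: SasaConfig = SasaConfig(),
                 np_gamma: float = DEFAULT_NP_GAMMA,
                 np_beta: float = DEFAULT_NP_BETA,
                 frame_index: int = 0) -> FrameEnergies:
    """Δ-terms of one frame: value(complex) − value(receptor) − value(ligand)."""
    lig = top.ligand_atoms
    rec = top.receptor_atoms
    if not lig or not rec:
        raise EnergeticsError("topology has no receptor/ligand partition")
    e_vdw, e_eel = lj_coulomb_interaction(top, frame, lig, rec)
    everything = lig | rec
    g_pol = (
        gb_polar_energy(top, frame, everything, gb_config)
        - gb_polar_energy(top, frame, rec, gb_config)
        - gb_polar_energy(top, frame, lig, gb_config)
    )
    g_np = (
        nonpolar_energy(sasa(top, frame, everything, sasa_config).total,
                        np_gamma, np_beta)
        - nonpolar_energy(sasa(top, frame, rec, sasa_config).total,
                          np_gamma, np_beta)
        - nonpolar_energy(sasa(top, frame, lig, sasa_config).total,
                          np_gamma, np_beta)
    )
    return FrameEnergies(e_vdw=e_vdw, e_eel=e_eel, g_polar=g_pol,
                         g_nonpolar=g_np, frame_index=frame_index)


def _retained(n_frames: int, discard) -> int:
    """First retained frame index for a discard fraction or count."""
    if isinstance(discard, float):
        if not 0.0 <= discard < 1.0:
            raise ValueError("discard fraction must be in [0, 1)")
        start = int(round(discard * n_frames))
    else:
        start = int(discard)
    if start < 0 or start >= n_frames:
        raise ValueError(
            f"discarding {start} frames leaves none of {n_frames}"
        )
    return start


def aggregate_replicas(per_frame: Sequence[Sequence[FrameEnergies]],
                       entropy: EntropyTerm | Sequence[EntropyTerm] | None,
                       discard=0.25) -> BindingEnergyComponents:
    """Average per-frame Δ-terms over replicas into the reported table.

    Each replica's retained frames (after discarding the equilibration
    window, default first 25%) are averaged; the reported mean is the
    mean of replica means and the spread is their sample standard
    deviation (0 for a single replica).  dg_bind is assembled as
    ΔE_vdw + ΔE_eel + ΔG_p + ΔG_np − TΔS exactly.
    """
    if not per_frame:
        raise ValueError("need at least one replica")
    replica_means = []
    start = None
    n_kept = None
    for frames in per_frame:
        frames = list(frames)
        start = _retained(len(frames), discard)
        kept = frames[start:]
        n_kept = len(kept)
        replica_means.append([
            np.mean([f.e_vdw for f in kept]),
            np.mean([f.e_eel for f in kept]),
            np.mean([f.g_polar for f in kept]),
            np.mean([f.g_nonpolar for f in kept]),
        ])
    m = np.array(replica_means)          # (n_rep, 4)
    n_rep = m.shape[0]
    means = m.mean(axis=0)
    spreads = m.std(axis=0, ddof=1) if n_rep > 1 else np.zeros(4)

    if entropy is None:
        tds = MeanSpread(0.0, 0.0)
    elif isinstance(entropy, EntropyTerm):
        tds = MeanSpread(entropy.t_delta_s, 0.0)
    else:
        vals = [e.t_delta_s for e in entropy]
        tds = MeanSpread(
            float(np.mean(vals)),
            float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
        )

    dg_mean = float(means.sum() - tds.mean)
    dg_spread = float(np.sqrt((spreads ** 2).sum() + tds.spread ** 2))
    return BindingEnergyComponents(
        de_vdw=MeanSpread(float(means[0]), float(spreads[0])),
        de_eel=MeanSpread(float(means[1]), float(spreads[1])),
        dg_polar=MeanSpread(float(means[2]), float(spreads[2])),
        dg_nonpolar=MeanSpread(float(means[3]), float(spreads[3])),
        t_delta_s=tds,
        dg_bind=MeanSpread(dg_mean, dg_spread),
        n_replicas=n_rep,
        frames_used=(start, n_kept),
    )


def assemble_components(de_vdw: float, de_eel: float, dg_polar: float,
                        dg_nonpolar: float, t_delta_s: float) -> float:
    """ΔG_bind from component means (ΔE_int ≡ 0, single trajectory)."""
    return de_vdw + de_eel + dg_polar + dg_nonpolar - t_delta_s


def per_residue_decomposition(top: Topology, traj: Trajectory,
                              gb_config: GBConfig = GBConfig(),
                              sasa_config: SasaConfig = SasaConfig(),
                              np_gamma: float = DEFAULT_NP_GAMMA,
                              ) -> list[ResidueContribution]:
    """Per-ligand-residue contributions to the binding energy (Fig-3 style).

    For each ligand residue: the LJ + Coulomb pair terms with the
    receptor, the GB cross terms (full pair energy attributed to the
    ligand residue), and γ times the residue's SASA change on binding;
    plus the time-averaged minimum heavy/any-atom distance to the
    receptor.
    """
    lig_residues = top.ligand_residues()
    rec = top.receptor_indices
    if rec.size == 0 or not lig_residues:
        raise EnergeticsError("topology has no receptor/ligand partition")
    lig = top.ligand_indices
    everything = np.arange(top.n_atoms)
    q = top.charges
    tau = 1.0 / gb_config.dielectric_in - 1.0 / gb_config.dielectric_out

    acc = {r: np.zeros(5) for r in lig_residues}  # vdw, eel, pol, np, dist
    for f in range(traj.n_frames):
        frame = traj.coordinates[f]
        # GB effective radii of the complex, reused for all residues
        reff = gb_effective_radii(
            top.array("born_radius"), top.array("gb_screen"), frame, gb_config
        )
        sasa_complex = sasa(top, frame, everything, sasa_config)
        sasa_ligand = sasa(top, frame, lig, sasa_config)
        area_c = dict(zip(sasa_complex.atom_indices.tolist(),
                          sasa_complex.per_atom_area))
        area_l = dict(zip(sasa_ligand.atom_indices.tolist(),
                          sasa_ligand.per_atom_area))
        for r in lig_residues:
            atoms_r = top.residue_atoms(r)
            e_vdw, e_eel = lj_coulomb_interaction(top, frame, atoms_r, rec)
            # GB cross term, ligand-side attribution (both pair orders)
            diff = frame[atoms_r][:, None, :] - frame[rec][None, :, :]
            r2 = (diff ** 2).sum(axis=2)
            rirj = reff[atoms_r][:, None] * reff[rec][None, :]
            fgb = np.sqrt(r2 + rirj * np.exp(-r2 / (4.0 * rirj)))
            e_pol = float(
                -COULOMB_CONSTANT * tau
                * np.sum(q[atoms_r][:, None] * q[rec][None, :] / fgb)
            )
            e_np = np_gamma * float(
                sum(area_c.get(int(i), 0.0) - area_l.get(int(i), 0.0)
                    for i in atoms_r)
            )
            min_dist = float(np.sqrt(r2.min()))
            acc[r] += np.array([e_vdw, e_eel, e_pol, e_np, min_dist])

    out = []
    nf = traj.n_frames
    for r in lig_residues:
        vdw, eel, pol, npo, dist = acc[r] / nf
        out.append(ResidueContribution(
            residue_index=r,
            energy=float(vdw + eel + pol + npo),
            mean_min_distance=float(dist),
            e_vdw=float(vdw), e_eel=float(eel),
            e_polar=float(pol), e_nonpolar=float(npo),
        ))
    return out


# ----------------------------------------------------------------------
# superposition and RMSF
# ----------------------------------------------------------------------

def kabsch_rotation(mobile: np.ndarray, target: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rotation R and centroids aligning mobile onto target."""
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    a = mobile - cm
    b = target - ct
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise ValueError("degenerate (colinear) fit coordinates")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return rot, cm, ct


def superpose_frames(traj: Trajectory, fit_group, reference: int = 0
                     ) -> np.ndarray:
    """All frames rigid-body fitted onto the reference over ``fit_group``."""
    fit = np.asarray(sorted(fit_group), dtype=int)
    ref = traj.coordinates[reference][fit]
    out = np.empty_like(traj.coordinates)
    for f in range(traj.n_frames):
        rot, cm, ct = kabsch_rotation(traj.coordinates[f][fit], ref)
        out[f] = (traj.coordinates[f] - cm) @ rot.T + ct
    return out


def representative_atom(top: Topology, residue_index: int) -> int:
    """Alpha-carbon when present, else the first heavy atom."""
    ca = top.find_atom(residue_index, "CA")
    if ca is not None:
        return ca
    for ai in top.residue_atoms(residue_index):
        if top.atoms[ai].element != "H":
            return int(ai)
    return int(top.residue_atoms(residue_index)[0])


def residue_rmsf(traj: Trajectory, group=None, reference: int = 0
                 ) -> np.ndarray:
    """Per-residue RMSF (Å) after superposition on ``group``.

    ``group`` is the fit selection (default: the receptor, falling back
    to all atoms for a monomer).  The RMSF is evaluated on each
    residue's representative atom (CA, else first heavy atom).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    top = traj.topology
    if group is None:
        group = top.receptor_atoms or set(range(top.n_atoms))
    fitted = superpose_frames(traj, group, reference)
    reps = [representative_atom(top, r) for r in range(top.n_residues)]
    coords = fitted[:, reps, :]              # (frames, residues, 3)
    mean = coords.mean(axis=0)
    return np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
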