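"""Conformational-ensemble observables.

Reaction coordinates (radius of gyration, end-to-end distance, SASA,
RMSD), a hydrogen-bond-pattern secondary-structure assignment mapped
to the three families helix / beta / coil, and intermolecular
residue–residue contact-occupancy maps.

Reaction coordinates are reported in nm / nm² (the reporting units);
all geometry is computed in Å internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .binding import kabsch_rotation
from .constants import ANGSTROM_PER_NM
from .sasa import SasaConfig, sasa
from .topology import Topology, Trajectory


class EnsembleError(ValueError):
    pass


@dataclass(frozen=True)
class EnsembleSeries:
    """Per-frame reaction coordinates in reporting units (nm, nm²)."""

    rg: np.ndarray
    e2e: np.ndarray
    sasa: np.ndarray
    rmsd: np.ndarray

    def __post_init__(self):
        n = len(self.rg)
        for name in ("e2e", "sasa", "rmsd"):
            if len(getattr(self, name)) != n:
                raise EnsembleError("series length mismatch")


def radius_of_gyration(top: Topology, frame: np.ndarray, group) -> float:
    """Mass-weighted radius of gyration, Å."""
    idx = np.asarray(sorted(group), dtype=int)
    if idx.size == 0:
        raise EnsembleError("empty group")
    m = top.masses[idx]
    x = np.asarray(frame, dtype=float)[idx]
    com = (m[:, None] * x).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((x - com) ** 2).sum(axis=1)).sum() / m.sum()))


def end_to_end_distance(top: Topology, frame: np.ndarray, group) -> float:
    """Distance between the first and last residue alpha-carbons, Å."""
    residues = sorted({top.atoms[int(i)].residue_index for i in group})
    first = top.find_atom(residues[0], "CA")
    last = top.find_atom(residues[-1], "CA")
    if first is None or last is None:
        raise EnsembleError(
            "terminal residues lack alpha-carbons for the end-to-end distance"
        )
    return float(np.linalg.norm(frame[last] - frame[first]))


def rmsd_to_reference(frame: np.ndarray, reference: np.ndarray, group
                      ) -> float:
    """Least-squares-fit RMSD over ``group``, Å."""
    idx = np.asarray(sorted(group), dtype=int)
    mob = np.asarray(frame, dtype=float)[idx]
    ref = np.asarray(reference, dtype=float)[idx]
    rot, cm, ct = kabsch_rotation(mob, ref)
    fitted = (mob - cm) @ rot.T + ct
    return float(np.sqrt(((fitted - ref) ** 2).sum(axis=1).mean()))


def reaction_coordinates(traj: Trajectory, group=None, reference: int = 0,
                         sasa_config: SasaConfig = SasaConfig()
                         ) -> EnsembleSeries:
    """Per-frame Rg, e2e, SASA and RMSD of ``group`` (nm / nm²)."""
    top = traj.topology
    if group is None:
        group = range(top.n_atoms)
    group = sorted(int(i) for i in group)
    if not group:
        raise EnsembleError("empty group")
    ref_frame = traj.coordinates[reference]
    rg, e2e, areas, rmsd = [], [], [], []
    for f in range(traj.n_frames):
        frame = traj.coordinates[f]
        rg.append(radius_of_gyration(top, frame, group))
        e2e.append(end_to_end_distance(top, frame, group))
        areas.append(sasa(top, frame, group, sasa_config).total)
        rmsd.append(rmsd_to_reference(frame, ref_frame, group))
    nm = ANGSTROM_PER_NM
    return EnsembleSeries(
        rg=np.array(rg) / nm,
        e2e=np.array(e2e) / nm,
        sasa=np.array(areas) / nm ** 2,
        rmsd=np.array(rmsd) / nm,
    )


# ----------------------------------------------------------------------
# Secondary structure: hydrogen-bond patterns (Kabsch–Sander energetics)
# mapped onto the three families helix / beta / coil.
# ----------------------------------------------------------------------

HBOND_ENERGY_CUTOFF = -0.5   # kcal/mol
_KS_FACTOR = 27.888          # 0.084 e² · 332 kcal·Å/mol
_CHAIN_BREAK_DISTANCE = 2.5  # Å between C(i-1) and N(i)


def _backbone_atoms(top: Topology, frame: np.ndarray):
    """Per-residue N/CA/C/O coordinates; None where the backbone is broken."""
    out = []
    for r in range(top.n_residues):
        coords = {}
        ok = True
        for name in ("N", "CA", "C", "O"):
            ai = top.find_atom(r, name)
            if ai is None:
                ok = False
                break
            coords[name] = frame[ai]
        out.append(coords if ok else None)
    return out


def _ks_hbonds(backbone, n_res: int) -> set[tuple[int, int]]:
    """(acceptor i, donor j) pairs with Kabsch–Sander energy < cutoff.

    The amide hydrogen of residue j is reconstructed 1 Å from N along
    the C=O direction of residue j−1; chain starts (including breaks
    detected by a long C(j−1)–N(j) distance) have no donor.
    """
    bonds: set[tuple[int, int]] = set()
    for j in range(n_res):
        bj = backbone[j]
        prev = backbone[j - 1] if j > 0 else None
        if bj is None or prev is None:
            continue
        if np.linalg.norm(bj["N"] - prev["C"]) > _CHAIN_BREAK_DISTANCE:
            continue
        co = prev["C"] - prev["O"]
        h = bj["N"] + co / np.linalg.norm(co)
        for i in range(n_res):
            if i == j or abs(i - j) < 2:
                continue
            bi = backbone[i]
            if bi is None:
                continue
            r_on = np.linalg.norm(bi["O"] - bj["N"])
            r_ch = np.linalg.norm(bi["C"] - h)
            r_oh = np.linalg.norm(bi["O"] - h)
            r_cn = np.linalg.norm(bi["C"] - bj["N"])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue  # clashing geometry, no defined H-bond
            energy = _KS_FACTOR * (1/r_on + 1/r_ch - 1/r_oh - 1/r_cn)
            if energy < HBOND_ENERGY_CUTOFF:
                bonds.add((i, j))
    return bonds


def assign_secondary_structure(top: Topology, frame: np.ndarray
                               ) -> np.ndarray:
    """Per-residue class in {"H", "E", "C"} for one frame.

    Helix: residues spanned by i→i+3 / i+4 / i+5 turn hydrogen bonds
    (3-10, alpha and pi families all count as helix).  Beta: residues
    in parallel or antiparallel bridge patterns.  Everything else,
    including residues with missing backbone atoms, is coil.  Helix
    takes priority over beta.
    """
    n = top.n_residues
    backbone = _backbone_atoms(top, frame)
    for r, b in enumerate(backbone):
        if b is None:
            warnings.warn(
                f"residue {r} lacks backbone atoms; classified as coil",
                stacklevel=2,
            )
    hb = _ks_hbonds(backbone, n)

    classes = np.full(n, "C", dtype="U1")

    def hbond(i, j):
        return 0 <= i < n and 0 <= j < n and (i, j) in hb

    # bridges first, helix overwrites
    for i in range(n):
        for j in range(i + 3, n):
            parallel = (
                (hbond(i - 1, j) and hbond(j, i + 1))
                or (hbond(j - 1, i) and hbond(i, j + 1))
            )
            antiparallel = (
                (hbond(i, j) and hbond(j, i))
                or (hbond(i - 1, j + 1) and hbond(j - 1, i + 1))
            )
            if parallel or antiparallel:
                classes[i] = "E"
                classes[j] = "E"
    for (i, j) in hb:
        if j - i in (3, 4, 5):
            classes[i + 1:j] = "H"
    return classes


@dataclass(frozen=True)
class SecondaryStructureProfile:
    """Per-frame-per-residue classes plus ensemble content percentages."""

    classes: np.ndarray        # (n_frames, n_residues) of "H"/"E"/"C"
    helix_percent: float
    beta_percent: float
    coil_percent: float

    @property
    def per_residue_propensity(self) -> dict[str, np.ndarray]:
        return {
            c: (self.classes == c).mean(axis=0) * 100.0
            for c in ("H", "E", "C")
        }


def secondary_structure_profile(top: Topology, traj: Trajectory
                                ) -> SecondaryStructureProfile:
    classes = np.stack([
        assign_secondary_structure(top, traj.coordinates[f])
        for f in range(traj.n_frames)
    ])
    total = classes.size
    return SecondaryStructureProfile(
        classes=classes,
        helix_percent=float((classes == "H").sum() / total * 100.0),
        beta_percent=float((classes == "E").sum() / total * 100.0),
        coil_percent=float((classes == "C").sum() / total * 100.0),
    )


# ----------------------------------------------------------------------
# Intermolecular residue–residue interaction map
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionMap:
    occupancy: np.ndarray          # (n_ligand_res, n_receptor_res) in [0,1]
    ligand_residues: np.ndarray
    receptor_residues: np.ndarray
    cutoff_nm: float


def interaction_map(top: Topology, traj: Trajectory,
                    cutoff_nm: float = 0.3,
                    heavy_atoms_only: bool = False) -> InteractionMap:
    """Contact occupancy per ligand-residue × receptor-residue pair.

    A pair is in contact in a frame iff the minimum distance between
    any atom of the ligand residue and any atom of the receptor
    residue is ≤ cutoff (default 0.3 nm); occupancy is the fraction of
    frames in contact.  Hydrogens count unless ``heavy_atoms_only``.
    """
    if cutoff_nm <= 0:
        raise EnsembleError("cutoff must be positive")
    cutoff = cutoff_nm * ANGSTROM_PER_NM

    def atoms_of(res):
        idx = top.residue_atoms(res)
        if heavy_atoms_only:
            idx = np.array(
                [i for i in idx if top.atoms[int(i)].element != "H"],
                dtype=int,
            )
        return idx

    lig_res = np.array(top.ligand_residues(), dtype=int)
    rec_res = np.array(top.receptor_residues(), dtype=int)
    lig_atoms = [atoms_of(r) for r in lig_res]
    rec_atoms = [atoms_of(r) for r in rec_res]

    counts = np.zeros((lig_res.size, rec_res.size))
    for f in range(traj.n_frames):
        frame = traj.coordinates[f]
        for a, la in enumerate(lig_atoms):
            diff = frame[la][:, None, :]
            for b, ra in enumerate(rec_atoms):
                d2 = ((diff - frame[ra][None, :, :]) ** 2).sum(axis=2)
                if d2.min() <= cutoff ** 2:
                    counts[a, b] += 1
    return InteractionMap(
        occupancy=counts / traj.n_frames,
        ligand_residues=lig_res,
        receptor_residues=rec_res,
        cutoff_nm=cutoff_nm,
    )
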