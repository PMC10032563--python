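"""Synthetic systems with known ground truth.

These generators stand in for the unavailable simulation data: a bound
peptide–receptor toy complex with harmonic positional fluctuations, a
two-basin bead-chain ensemble with prescribed mixture weights in
(end-to-end, Rg) space, ideal helical / extended / paired-strand
backbones for the secondary-structure assignment, and Gaussian
interaction-energy series.  Everything is a pure function of its
arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .topology import Atom, ResidueSpan, Topology, Trajectory

_FRAME_SPACING_PS = 10.0   # trajectory-saving interval emulated here


@dataclass(frozen=True)
class ToySpec:
    n_receptor_atoms: int = 30
    n_ligand_atoms: int = 10
    charge_scale: float = 0.5      # e
    jitter_sigma: float = 0.3      # Å
    n_frames: int = 50
    seed: int = 0
    mixture_weights: tuple[float, float] = (0.8, 0.2)
    zero_charges: bool = False

    def __post_init__(self):
        if self.n_receptor_atoms < 1 or self.n_ligand_atoms < 1:
            raise ValueError("atom counts must be >= 1")
        if self.jitter_sigma < 0:
            raise ValueError("sigma must be non-negative")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


# plausible per-element parameter rows: (rmin/2 Å, eps kcal/mol,
# born radius Å, screen, mass amu)
_ELEMENT_TABLE = {
    "C": (1.9080, 0.1094, 1.70, 0.72, 12.011),
    "N": (1.8240, 0.1700, 1.55, 0.79, 14.007),
    "O": (1.6612, 0.2100, 1.50, 0.85, 15.999),
    "S": (2.0000, 0.2500, 1.80, 0.96, 32.06),
}
_ELEMENT_CYCLE = ("C", "N", "O", "C", "S")


def _make_atoms(n: int, offset: int, res_offset: int, atoms_per_res: int,
                charges: np.ndarray, prefix: str) -> list[Atom]:
    atoms = []
    for i in range(n):
        element = _ELEMENT_CYCLE[i % len(_ELEMENT_CYCLE)]
        rmh, eps, born, screen, mass = _ELEMENT_TABLE[element]
        atoms.append(Atom(
            index=offset + i,
            name=f"{element}{i % atoms_per_res + 1}",
            residue_index=res_offset + i // atoms_per_res,
            element=element,
            charge=float(charges[i]),
            lj_rmin_half=rmh,
            lj_epsilon=eps,
            born_radius=born,
            gb_screen=screen,
            mass=mass,
        ))
    return atoms


def build_toy_complex(spec: ToySpec) -> tuple[Topology, np.ndarray]:
    """A bound pose: receptor lattice plus a ligand chain in a groove.

    Receptor atoms sit on a jittered cubic lattice (4 Å spacing);
    ligand beads run along a line 4 Å above the top lattice face, so
    every ligand atom is 3–5 Å from its nearest receptor neighbor.
    Charges are drawn within ±charge_scale (or all zero); the
    ligand/receptor partition is pre-set.
    """
    rng = np.random.default_rng(spec.seed)
    n_rec, n_lig = spec.n_receptor_atoms, spec.n_ligand_atoms

    side = int(np.ceil(n_rec ** (1.0 / 3.0)))
    grid = np.array(
        [(i, j, k) for k in range(side) for j in range(side)
         for i in range(side)][:n_rec], dtype=float
    ) * 4.0
    grid += rng.normal(0.0, 0.25, grid.shape)

    # serpentine ligand chain over the top lattice face so every bead
    # stays within nonbonded contact of the receptor surface
    top_z = grid[:, 2].max()
    per_row = max(1, int(grid[:, 0].max() // 3.8) + 1)
    lig_coords = np.zeros((n_lig, 3))
    lig_coords[:, 0] = 2.0 + 3.8 * (np.arange(n_lig) % per_row)
    lig_coords[:, 1] = 2.0 + 3.8 * (np.arange(n_lig) // per_row)
    lig_coords[:, 2] = top_z + 4.0
    pose = np.vstack([grid, lig_coords])

    if spec.zero_charges:
        charges = np.zeros(n_rec + n_lig)
    else:
        charges = rng.uniform(
            -spec.charge_scale, spec.charge_scale, n_rec + n_lig
        )
        # neutralize each side so long-range interactions vanish on
        # separation (no monopole term)
        charges[:n_rec] -= charges[:n_rec].mean()
        charges[n_rec:] -= charges[n_rec:].mean()

    rec_per_res = 5
    n_rec_res = int(np.ceil(n_rec / rec_per_res))
    lig_per_res = 2
    rec_atoms = _make_atoms(n_rec, 0, 0, rec_per_res, charges[:n_rec], "R")
    lig_atoms = _make_atoms(
        n_lig, n_rec, n_rec_res, lig_per_res, charges[n_rec:], "L"
    )
    atoms = rec_atoms + lig_atoms

    residues = []
    for r in range(n_rec_res):
        first = r * rec_per_res
        last = min(first + rec_per_res, n_rec) - 1
        residues.append(ResidueSpan("REC", first, last))
    n_lig_res = int(np.ceil(n_lig / lig_per_res))
    for r in range(n_lig_res):
        first = n_rec + r * lig_per_res
        last = n_rec + min((r + 1) * lig_per_res, n_lig) - 1
        residues.append(ResidueSpan("LIG", first, last))

    topology = Topology(
        atoms=tuple(atoms),
        residues=tuple(residues),
        ligand_atoms=frozenset(range(n_rec, n_rec + n_lig)),
        receptor_atoms=frozenset(range(n_rec)),
    )
    return topology, pose


def sample_harmonic_ensemble(topology: Topology, pose: np.ndarray,
                             sigma: float, n_frames: int, seed: int
                             ) -> Trajectory:
    """Frames = pose + i.i.d. Gaussian displacement (σ per coordinate)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    pose = np.asarray(pose, dtype=float)
    coords = pose[None, :, :] + rng.normal(
        0.0, sigma, (n_frames,) + pose.shape
    ) if sigma > 0 else np.repeat(pose[None], n_frames, axis=0)
    return Trajectory(
        coordinates=coords,
        frame_times=_FRAME_SPACING_PS * np.arange(n_frames),
        topology=topology,
    )


def gaussian_energy_series(mean: float, sigma: float, n_frames: int,
                           seed: int) -> np.ndarray:
    """Gaussian per-frame interaction-energy series, kcal/mol."""
    rng = np.random.default_rng(seed)
    return rng.normal(mean, sigma, n_frames)


# ----------------------------------------------------------------------
# Two-state bead chain with prescribed (e2e, Rg) basins
# ----------------------------------------------------------------------

_BOND_LENGTH = 3.8  # Å, CA-CA virtual bond


def _helix_chain(alpha: float, rise: float, n_beads: int) -> np.ndarray:
    """Bead chain on a regular helix: turn angle α and rise per bead."""
    chord = _BOND_LENGTH ** 2 - rise ** 2
    chord = max(chord, 1e-12)
    radius = np.sqrt(chord) / (2.0 * np.sin(alpha / 2.0))
    t = np.arange(n_beads)
    return np.stack([
        radius * np.cos(alpha * t),
        radius * np.sin(alpha * t),
        rise * t,
    ], axis=1)


def _chain_coordinates(coords: np.ndarray) -> tuple[float, float]:
    e2e = float(np.linalg.norm(coords[-1] - coords[0]))
    com = coords.mean(axis=0)
    rg = float(np.sqrt(((coords - com) ** 2).sum(axis=1).mean()))
    return e2e, rg


def _solve_chain(e2e_target: float, rg_target: float, n_beads: int,
                 x0=None) -> np.ndarray:
    """Find helix parameters whose chain matches the (e2e, Rg) target."""
    contour = (n_beads - 1) * _BOND_LENGTH
    if e2e_target > contour:
        raise ValueError(
            f"end-to-end target {e2e_target:.1f} Å exceeds the chain "
            f"contour length {contour:.1f} Å"
        )

    def residual(params):
        alpha, rise = params
        e2e, rg = _chain_coordinates(_helix_chain(alpha, rise, n_beads))
        return [e2e - e2e_target, rg - rg_target]

    starts = [x0] if x0 is not None else []
    starts += [(1.0, 0.5 * _BOND_LENGTH), (0.4, 0.9 * _BOND_LENGTH),
               (2.0, 0.2 * _BOND_LENGTH)]
    best = None
    for start in starts:
        sol = least_squares(
            residual, start,
            bounds=([1e-3, 0.0], [np.pi - 1e-3, _BOND_LENGTH - 1e-6]),
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-6:
            break
    return best.x


def chain_topology(n_beads: int) -> Topology:
    """One CA bead per residue; used by the two-state generator."""
    atoms = tuple(
        Atom(index=i, name="CA", residue_index=i, element="C",
             charge=0.0, lj_rmin_half=1.9080, lj_epsilon=0.1094,
             born_radius=1.7, gb_screen=0.72, mass=12.011)
        for i in range(n_beads)
    )
    residues = tuple(ResidueSpan("GLY", i, i) for i in range(n_beads))
    return Topology(atoms=atoms, residues=residues,
                    ligand_atoms=frozenset(range(n_beads)),
                    receptor_atoms=frozenset())


#: Default basins in Å (e2e, Rg): a compact helix-like state and a more
#: extended state, sitting inside the 0.9–1.2 nm Rg / 1.0–2.5 nm e2e
#: region where the R2 monomer's landscape minima live.
DEFAULT_BASINS = ((10.0, 9.0), (25.0, 12.0))


def sample_two_state_chain(basins=DEFAULT_BASINS,
                           weights=(0.8, 0.2),
                           noise: float = 0.5,
                           n_frames: int = 2000,
                           seed: int = 0,
                           n_beads: int = 16) -> tuple[Trajectory, np.ndarray]:
    """Bead-chain ensemble hopping between two (e2e, Rg) basins.

    Per frame a basin is chosen by its weight, the frame's (e2e, Rg)
    target is the basin center plus Gaussian noise (σ = ``noise`` Å on
    both coordinates), and a helical bead chain matching that target is
    emitted with a random rigid-body orientation.  Returns the
    trajectory and the per-frame basin labels.
    """
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    rng = np.random.default_rng(seed)
    top = chain_topology(n_beads)
    warm = [_solve_chain(e, r, n_beads) for (e, r) in basins]

    labels = rng.choice(len(weights), size=n_frames, p=np.asarray(weights))
    frames = np.empty((n_frames, n_beads, 3))
    for f in range(n_frames):
        b = int(labels[f])
        e_t = basins[b][0] + rng.normal(0.0, noise)
        r_t = basins[b][1] + rng.normal(0.0, noise)
        e_t = min(max(e_t, 1.0), (n_beads - 1) * _BOND_LENGTH - 0.1)
        params = _solve_chain(e_t, r_t, n_beads, x0=warm[b])
        chain = _helix_chain(params[0], params[1], n_beads)
        # random proper rotation: QR of a Gaussian matrix
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        frames[f] = (chain - chain.mean(axis=0)) @ q.T
    traj = Trajectory(
        coordinates=frames,
        frame_times=_FRAME_SPACING_PS * np.arange(n_frames),
        topology=top,
    )
    return traj, labels


# ----------------------------------------------------------------------
# Ideal peptide backbones (N, CA, C, O) at prescribed torsions
# ----------------------------------------------------------------------

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = np.deg2rad(111.2)
_ANGLE_CA_C_N = np.deg2rad(116.6)
_ANGLE_C_N_CA = np.deg2rad(121.9)
_ANGLE_CA_C_O = np.deg2rad(120.8)
_OMEGA = np.deg2rad(180.0)

_BACKBONE_PARAMS = {
    "N": ("N", 14.007, 1.55, 0.79),
    "CA": ("C", 12.011, 1.70, 0.72),
    "C": ("C", 12.011, 1.70, 0.72),
    "O": ("O", 15.999, 1.50, 0.85),
}


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension reference frame placement of the next atom."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_ideal_backbone(n_res: int, phi: float, psi: float
                         ) -> tuple[Topology, np.ndarray]:
    """Full backbone (N, CA, C, O) at uniform (φ, ψ), ω = 180°.

    (−57, −47) gives an ideal alpha-helix; (−180, 180) a fully
    extended chain.  Angles in degrees.
    """
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    phi_r, psi_r = np.deg2rad(phi), np.deg2rad(psi)

    n_pos = np.array([0.0, 0.0, 0.0])
    ca_pos = np.array([_BOND_N_CA, 0.0, 0.0])
    c_pos = ca_pos + _BOND_CA_C * np.array([
        np.cos(np.pi - _ANGLE_N_CA_C), np.sin(np.pi - _ANGLE_N_CA_C), 0.0
    ])

    coords: list[np.ndarray] = []
    names: list[str] = []
    res_of: list[int] = []

    def add(name, pos, r):
        coords.append(pos)
        names.append(name)
        res_of.append(r)

    for r in range(n_res):
        o_pos = _place(n_pos, ca_pos, c_pos, _BOND_C_O, _ANGLE_CA_C_O,
                       psi_r + np.pi)
        add("N", n_pos, r)
        add("CA", ca_pos, r)
        add("C", c_pos, r)
        add("O", o_pos, r)
        if r == n_res - 1:
            break
        n_next = _place(n_pos, ca_pos, c_pos, _BOND_C_N, _ANGLE_CA_C_N, psi_r)
        ca_next = _place(ca_pos, c_pos, n_next, _BOND_N_CA, _ANGLE_C_N_CA,
                         _OMEGA)
        c_next = _place(c_pos, n_next, ca_next, _BOND_CA_C, _ANGLE_N_CA_C,
                        phi_r)
        n_pos, ca_pos, c_pos = n_next, ca_next, c_next

    atoms = []
    for i, (name, r) in enumerate(zip(names, res_of)):
        element, mass, born, screen = _BACKBONE_PARAMS[name]
        atoms.append(Atom(
            index=i, name=name, residue_index=r, element=element,
            charge=0.0, lj_rmin_half=1.7, lj_epsilon=0.1,
            born_radius=born, gb_screen=screen, mass=mass,
        ))
    spans = []
    for r in range(n_res):
        idx = [i for i, rr in enumerate(res_of) if rr == r]
        spans.append(ResidueSpan("ALA", min(idx), max(idx)))
    topology = Topology(atoms=tuple(atoms), residues=tuple(spans),
                        ligand_atoms=frozenset(range(len(atoms))),
                        receptor_atoms=frozenset())
    return topology, np.array(coords)


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def build_antiparallel_sheet(n_res: int = 6
                             ) -> tuple[Topology, np.ndarray]:
    """Two antiparallel beta strands with an inter-strand H-bond ladder.

    Strand A is an ideal strand at sheet torsions (−139, 135); strand B
    starts as its two-fold rotation about the strand axis (reversing
    chain sense) and is then rolled about that axis, slid along it and
    offset sideways over a deterministic grid, keeping the placement
    with the most inter-strand backbone hydrogen bonds.
    """
    from .ensemble import _backbone_atoms, _ks_hbonds  # no cycle at runtime

    top_a, xyz_a = build_ideal_backbone(n_res, -139.0, 135.0)

    atoms = list(top_a.atoms)
    n_at = len(atoms)
    for a in top_a.atoms:
        atoms.append(Atom(
            index=n_at + a.index, name=a.name,
            residue_index=n_res + a.residue_index, element=a.element,
            charge=a.charge, lj_rmin_half=a.lj_rmin_half,
            lj_epsilon=a.lj_epsilon, born_radius=a.born_radius,
            gb_screen=a.gb_screen, mass=a.mass,
        ))
    spans = list(top_a.residues) + [
        ResidueSpan(s.name, s.first_atom + n_at, s.last_atom + n_at)
        for s in top_a.residues
    ]
    top = Topology(atoms=tuple(atoms), residues=tuple(spans),
                   ligand_atoms=frozenset(range(len(atoms))),
                   receptor_atoms=frozenset())

    ca = xyz_a[1::4]
    frame = np.linalg.svd(ca - ca.mean(axis=0))[2]
    axis, perp = frame[0], frame[1]
    normal = np.cross(axis, perp)
    center = xyz_a.mean(axis=0)
    flip = _axis_rotation(axis, np.pi)

    def assemble(roll_deg, dx, dp, dn):
        rot = _axis_rotation(axis, np.deg2rad(roll_deg)) @ flip
        xyz_b = ((xyz_a - center) @ rot.T + center
                 + dx * axis + dp * perp + dn * normal)
        return np.vstack([xyz_a, xyz_b])

    best = (-1, (0.0, 0.0, 4.85, 0.0))
    for roll in range(0, 360, 15):
        for dx in np.arange(-4.0, 4.01, 0.5):
            for dp in (4.5, 4.85, 5.2):
                for dn in np.arange(-1.5, 1.51, 0.5):
                    xyz = assemble(roll, dx, dp, dn)
                    hb = _ks_hbonds(
                        _backbone_atoms(top, xyz), top.n_residues
                    )
                    inter = sum(
                        1 for (i, j) in hb if (i < n_res) != (j < n_res)
                    )
                    if inter > best[0]:
                        best = (inter, (roll, dx, dp, dn))
    return top, assemble(*best[1])
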