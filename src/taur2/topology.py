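"""Atomistic topology and trajectory containers.

The topology carries exactly the per-atom parameters the end-point
energy terms need (partial charge, Lennard-Jones rmin/2 and epsilon,
intrinsic generalized-Born radius and screening factor, a van der
Waals radius for surface areas) plus the residue table and the
ligand/receptor partition of the complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import yaml


class TopologyError(ValueError):
    """Malformed or inconsistent topology input."""


class ConsistencyError(TopologyError):
    """Counts or cross-references in an input file disagree."""


#: Fallback van der Waals radii (Å) when the LJ rmin/2 is absent or zero.
ELEMENT_VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
}

ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974,
}


def element_from_name(name: str) -> str:
    """Infer the element from a PDB-style atom name."""
    stripped = name.strip()
    for ch in stripped:
        if ch.isalpha():
            upper = ch.upper()
            # two-letter sulfur/phosphorus are written S../P.. in our systems
            return upper
    raise TopologyError(f"cannot infer element from atom name {name!r}")


@dataclass(frozen=True)
class Atom:
    """One particle with the parameters entering the MM-GBSA terms."""

    index: int
    name: str
    residue_index: int
    element: str
    charge: float = 0.0          # elementary charges
    lj_rmin_half: float = 0.0    # Å
    lj_epsilon: float = 0.0      # kcal/mol
    born_radius: float = 1.5     # Å
    gb_screen: float = 0.8       # dimensionless
    vdw_radius: float | None = None  # Å; defaults to lj_rmin_half
    mass: float | None = None    # amu; defaults from the element

    def __post_init__(self):
        if self.lj_epsilon < 0:
            raise TopologyError(f"atom {self.index}: negative LJ epsilon")
        if self.born_radius <= 0:
            raise TopologyError(f"atom {self.index}: non-positive Born radius")
        if self.vdw_radius is None:
            r = self.lj_rmin_half
            if r <= 0:
                r = ELEMENT_VDW_RADII.get(self.element, 1.7)
            object.__setattr__(self, "vdw_radius", r)
        if self.vdw_radius <= 0:
            raise TopologyError(f"atom {self.index}: non-positive vdW radius")
        if self.mass is None:
            object.__setattr__(
                self, "mass", ELEMENT_MASSES.get(self.element, 12.011)
            )


class ResidueSpan(NamedTuple):
    name: str
    first_atom: int  # inclusive, 0-based
    last_atom: int   # inclusive, 0-based


@dataclass(frozen=True)
class Topology:
    """Ordered atoms, residue table and the receptor/ligand partition.

    ``ligand_atoms`` and ``receptor_atoms`` are disjoint and together
    cover every atom; a monomer system may leave the receptor empty.
    """

    atoms: tuple[Atom, ...]
    residues: tuple[ResidueSpan, ...]
    ligand_atoms: frozenset[int] = frozenset()
    receptor_atoms: frozenset[int] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))
        object.__setattr__(self, "residues", tuple(self.residues))
        object.__setattr__(self, "ligand_atoms", frozenset(self.ligand_atoms))
        object.__setattr__(
            self, "receptor_atoms", frozenset(self.receptor_atoms)
        )
        self.validate()

    # -- invariants -------------------------------------------------
    def validate(self) -> None:
        n = len(self.atoms)
        for i, atom in enumerate(self.atoms):
            if atom.index != i:
                raise ConsistencyError(
                    f"atom at position {i} has index {atom.index}"
                )
        cursor = 0
        for ri, span in enumerate(self.residues):
            if span.first_atom != cursor or span.last_atom < span.first_atom:
                raise ConsistencyError(
                    f"residue {ri} span {span.first_atom}..{span.last_atom} "
                    f"does not tile the atom list (expected start {cursor})"
                )
            for ai in range(span.first_atom, span.last_atom + 1):
                if self.atoms[ai].residue_index != ri:
                    raise ConsistencyError(
                        f"atom {ai} claims residue "
                        f"{self.atoms[ai].residue_index}, span says {ri}"
                    )
            cursor = span.last_atom + 1
        if cursor != n:
            raise ConsistencyError(
                f"residue spans cover {cursor} atoms, topology has {n}"
            )
        if self.ligand_atoms or self.receptor_atoms:
            if self.ligand_atoms & self.receptor_atoms:
                raise ConsistencyError("ligand and receptor sets overlap")
            if self.ligand_atoms | self.receptor_atoms != set(range(n)):
                raise ConsistencyError(
                    "ligand ∪ receptor does not cover all solute atoms"
                )

    # -- convenience accessors --------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def array(self, attr: str) -> np.ndarray:
        return np.array([getattr(a, attr) for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return self.array("charge")

    @property
    def masses(self) -> np.ndarray:
        return self.array("mass")

    @property
    def ligand_indices(self) -> np.ndarray:
        return np.array(sorted(self.ligand_atoms), dtype=int)

    @property
    def receptor_indices(self) -> np.ndarray:
        return np.array(sorted(self.receptor_atoms), dtype=int)

    def residue_atoms(self, residue_index: int) -> np.ndarray:
        span = self.residues[residue_index]
        return np.arange(span.first_atom, span.last_atom + 1)

    def ligand_residues(self) -> list[int]:
        return sorted(
            {self.atoms[i].residue_index for i in self.ligand_atoms}
        )

    def receptor_residues(self) -> list[int]:
        return sorted(
            {self.atoms[i].residue_index for i in self.receptor_atoms}
        )

    def find_atom(self, residue_index: int, name: str) -> int | None:
        for ai in self.residue_atoms(residue_index):
            if self.atoms[ai].name.strip() == name:
                return int(ai)
        return None


def select_partition(topology: Topology, ligand_residues: Iterable[int]) -> Topology:
    """Return a topology whose ligand is the atoms of the given residues.

    Every other atom becomes the receptor. The selection must leave both
    sides non-empty (a complex needs two partners).
    """
    wanted = set(int(r) for r in ligand_residues)
    if not wanted:
        raise TopologyError("empty ligand residue selection")
    bad = wanted - set(range(topology.n_residues))
    if bad:
        raise TopologyError(f"ligand residues out of range: {sorted(bad)}")
    ligand = {
        int(i)
        for r in wanted
        for i in topology.residue_atoms(r)
    }
    receptor = set(range(topology.n_atoms)) - ligand
    if not receptor:
        raise TopologyError("selection covers every residue; receptor empty")
    return replace(
        topology,
        ligand_atoms=frozenset(ligand),
        receptor_atoms=frozenset(receptor),
    )


@dataclass(frozen=True)
class Trajectory:
    """Frames of Cartesian coordinates (Å) over a fixed topology."""

    coordinates: np.ndarray        # (n_frames, n_atoms, 3), Å
    frame_times: np.ndarray        # ps
    topology: Topology

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        times = np.asarray(self.frame_times, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ConsistencyError("coordinates must be (frames, atoms, 3)")
        if coords.shape[1] != self.topology.n_atoms:
            raise ConsistencyError(
                f"frames carry {coords.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}"
            )
        if times.shape != (coords.shape[0],):
            raise ConsistencyError("frame_times length mismatch")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ConsistencyError("frame_times must be strictly increasing")
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "frame_times", times)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    def __getitem__(self, frame: int) -> np.ndarray:
        return self.coordinates[frame]


# ----------------------------------------------------------------------
# Native structured topology file (YAML)
# ----------------------------------------------------------------------

def write_topology_yaml(topology: Topology, path) -> None:
    """Write the native key-value topology format (YAML)."""
    doc = {
        "atoms": [
            {
                "name": a.name,
                "residue": a.residue_index,
                "element": a.element,
                "charge": float(a.charge),
                "lj_rmin_half": float(a.lj_rmin_half),
                "lj_epsilon": float(a.lj_epsilon),
                "born_radius": float(a.born_radius),
                "gb_screen": float(a.gb_screen),
                "vdw_radius": float(a.vdw_radius),
                "mass": float(a.mass),
            }
            for a in topology.atoms
        ],
        "residues": [
            {"name": r.name, "first_atom": r.first_atom, "last_atom": r.last_atom}
            for r in topology.residues
        ],
        "ligand_atoms": sorted(topology.ligand_atoms),
        "receptor_atoms": sorted(topology.receptor_atoms),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_topology_yaml(path) -> Topology:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for key in ("atoms", "residues"):
        if key not in doc:
            raise TopologyError(f"topology file missing section {key!r}")
    atoms = tuple(
        Atom(
            index=i,
            name=rec["name"],
            residue_index=int(rec["residue"]),
            element=rec["element"],
            charge=float(rec.get("charge", 0.0)),
            lj_rmin_half=float(rec.get("lj_rmin_half", 0.0)),
            lj_epsilon=float(rec.get("lj_epsilon", 0.0)),
            born_radius=float(rec.get("born_radius", 1.5)),
            gb_screen=float(rec.get("gb_screen", 0.8)),
            vdw_radius=rec.get("vdw_radius"),
            mass=rec.get("mass"),
        )
        for i, rec in enumerate(doc["atoms"])
    )
    residues = tuple(
        ResidueSpan(r["name"], int(r["first_atom"]), int(r["last_atom"]))
        for r in doc["residues"]
    )
    return Topology(
        atoms=atoms,
        residues=residues,
        ligand_atoms=frozenset(doc.get("ligand_atoms", ())),
        receptor_atoms=frozenset(doc.get("receptor_atoms", ())),
    )
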