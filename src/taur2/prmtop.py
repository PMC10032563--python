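"""AMBER parm7 (prmtop) subset reader and writer.

Only the sections needed for end-point nonbonded energetics are
handled: charges, atom names, residue table, Lennard-Jones type maps
and A/B coefficient tables, and the generalized-Born radii and
screening factors.  Bonded sections are ignored: under the
single-trajectory sampling protocol the internal-energy change cancels
exactly, so bonded parameters never enter the analysis.
"""

from __future__ import annotations

import re

import numpy as np

from .constants import PRMTOP_CHARGE_SCALE
from .topology import (
    Atom,
    ConsistencyError,
    ResidueSpan,
    Topology,
    TopologyError,
    element_from_name,
)

REQUIRED_FLAGS = (
    "POINTERS",
    "CHARGE",
    "ATOM_NAME",
    "RESIDUE_LABEL",
    "RESIDUE_POINTER",
    "ATOM_TYPE_INDEX",
    "NONBONDED_PARM_INDEX",
    "LENNARD_JONES_ACOEF",
    "LENNARD_JONES_BCOEF",
    "RADII",
    "SCREEN",
)

_A4_FORMAT = re.compile(r"\(\s*(\d+)[aA](\d+)\s*\)")


class PrmtopFormatError(TopologyError):
    """A required %FLAG section is missing or malformed."""


def _split_sections(text: str) -> dict[str, tuple[str, list[str]]]:
    sections: dict[str, tuple[str, list[str]]] = {}
    current = None
    fmt = ""
    body: list[str] = []
    for line in text.splitlines():
        if line.startswith("%VERSION"):
            continue
        if line.startswith("%FLAG"):
            if current is not None:
                sections[current] = (fmt, body)
            current = line.split()[1]
            fmt, body = "", []
        elif line.startswith("%FORMAT"):
            fmt = line[len("%FORMAT"):].strip()
        elif line.startswith("%COMMENT"):
            continue
        elif current is not None:
            body.append(line)
    if current is not None:
        sections[current] = (fmt, body)
    return sections


def _parse_numeric(body: list[str], dtype) -> np.ndarray:
    tokens: list[str] = []
    for line in body:
        tokens.extend(line.split())
    return np.array(tokens, dtype=dtype)


def _parse_a4(fmt: str, body: list[str]) -> list[str]:
    m = _A4_FORMAT.search(fmt)
    width = int(m.group(2)) if m else 4
    out: list[str] = []
    for line in body:
        for start in range(0, len(line.rstrip("\n")), width):
            piece = line[start:start + width]
            if piece.strip():
                out.append(piece.strip())
    return out


def read_prmtop_subset(path) -> Topology:
    """Read the nonbonded-parameter subset of an AMBER parm7 file.

    Charges are converted from the file's internal units to elementary
    charges (division by 18.2223); per-atom LJ rmin/2 and epsilon are
    recovered from the diagonal entries of the A/B coefficient tables
    through the type-index maps.
    """
    with open(path) as fh:
        sections = _split_sections(fh.read())

    for flag in REQUIRED_FLAGS:
        if flag not in sections:
            raise PrmtopFormatError(f"prmtop is missing %FLAG {flag}")

    pointers = _parse_numeric(sections["POINTERS"][1], int)
    if pointers.size < 12:
        raise PrmtopFormatError("POINTERS section too short")
    n_atoms = int(pointers[0])
    n_types = int(pointers[1])
    n_res = int(pointers[11])

    charges = _parse_numeric(sections["CHARGE"][1], float) / PRMTOP_CHARGE_SCALE
    names = _parse_a4(*sections["ATOM_NAME"])
    res_labels = _parse_a4(*sections["RESIDUE_LABEL"])
    res_pointers = _parse_numeric(sections["RESIDUE_POINTER"][1], int)
    type_index = _parse_numeric(sections["ATOM_TYPE_INDEX"][1], int)
    nb_index = _parse_numeric(sections["NONBONDED_PARM_INDEX"][1], int)
    acoef = _parse_numeric(sections["LENNARD_JONES_ACOEF"][1], float)
    bcoef = _parse_numeric(sections["LENNARD_JONES_BCOEF"][1], float)
    radii = _parse_numeric(sections["RADII"][1], float)
    screen = _parse_numeric(sections["SCREEN"][1], float)

    for label, arr, expect in (
        ("CHARGE", charges, n_atoms),
        ("ATOM_NAME", names, n_atoms),
        ("ATOM_TYPE_INDEX", type_index, n_atoms),
        ("RADII", radii, n_atoms),
        ("SCREEN", screen, n_atoms),
        ("RESIDUE_LABEL", res_labels, n_res),
        ("RESIDUE_POINTER", res_pointers, n_res),
        ("NONBONDED_PARM_INDEX", nb_index, n_types * n_types),
    ):
        if len(arr) != expect:
            raise ConsistencyError(
                f"{label} holds {len(arr)} entries, POINTERS implies {expect}"
            )

    masses = None
    if "MASS" in sections:
        masses = _parse_numeric(sections["MASS"][1], float)
        if len(masses) != n_atoms:
            raise ConsistencyError("MASS length disagrees with POINTERS")
    atomic_numbers = None
    if "ATOMIC_NUMBER" in sections:
        atomic_numbers = _parse_numeric(sections["ATOMIC_NUMBER"][1], int)

    # diagonal A/B entry for each atom's LJ type
    rmin_half = np.zeros(n_atoms)
    epsilon = np.zeros(n_atoms)
    for i in range(n_atoms):
        t = int(type_index[i])  # 1-based
        ico = int(nb_index[n_types * (t - 1) + (t - 1)])
        if ico <= 0:
            continue  # 10-12 potential slot; leave LJ zero
        a, b = acoef[ico - 1], bcoef[ico - 1]
        if a > 0 and b > 0:
            rmin_ii = (2.0 * a / b) ** (1.0 / 6.0)
            rmin_half[i] = rmin_ii / 2.0
            epsilon[i] = b * b / (4.0 * a)

    _Z_TO_ELEMENT = {1: "H", 6: "C", 7: "N", 8: "O", 15: "P", 16: "S"}
    atoms = []
    for i in range(n_atoms):
        if atomic_numbers is not None:
            element = _Z_TO_ELEMENT.get(int(atomic_numbers[i]))
            if element is None:
                element = element_from_name(names[i])
        else:
            element = element_from_name(names[i])
        atoms.append(
            Atom(
                index=i,
                name=names[i],
                residue_index=0,  # patched below
                element=element,
                charge=float(charges[i]),
                lj_rmin_half=float(rmin_half[i]),
                lj_epsilon=float(epsilon[i]),
                born_radius=float(radii[i]),
                gb_screen=float(screen[i]),
                mass=float(masses[i]) if masses is not None else None,
            )
        )

    residues = []
    for r in range(n_res):
        first = int(res_pointers[r]) - 1
        last = (int(res_pointers[r + 1]) - 2) if r + 1 < n_res else n_atoms - 1
        if first < 0 or last < first:
            raise ConsistencyError(f"RESIDUE_POINTER invalid at residue {r}")
        residues.append(ResidueSpan(res_labels[r], first, last))
        for ai in range(first, last + 1):
            atoms[ai] = Atom(
                **{**atoms[ai].__dict__, "residue_index": r}
            )

    return Topology(atoms=tuple(atoms), residues=tuple(residues))


def _chunk_lines(values, per_line: int, fmt: str) -> list[str]:
    lines = []
    for start in range(0, len(values), per_line):
        lines.append("".join(fmt % v for v in values[start:start + per_line]))
    if not lines:
        lines = [""]
    return lines


def write_prmtop_subset(topology: Topology, path) -> None:
    """Write the parm7 subset this package reads (round-trip partner).

    Every atom is given its own LJ type; the A/B tables therefore hold
    the full lower triangle built with Lorentz–Berthelot combination.
    """
    n = topology.n_atoms
    n_types = n
    pointers = [0] * 31
    pointers[0] = n
    pointers[1] = n_types
    pointers[11] = topology.n_residues

    rmh = topology.array("lj_rmin_half")
    eps = topology.array("lj_epsilon")
    acoef, bcoef = [], []
    for i in range(n_types):
        for j in range(i + 1):
            rmin_ij = rmh[i] + rmh[j]
            eps_ij = np.sqrt(eps[i] * eps[j])
            acoef.append(eps_ij * rmin_ij ** 12)
            bcoef.append(2.0 * eps_ij * rmin_ij ** 6)
    nb_index = np.zeros(n_types * n_types, dtype=int)
    for i in range(n_types):
        for j in range(n_types):
            lo, hi = min(i, j), max(i, j)
            nb_index[n_types * i + j] = hi * (hi + 1) // 2 + lo + 1

    _ELEMENT_TO_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16}

    def a4(values):
        return _chunk_lines([f"{v:<4s}" for v in values], 20, "%s")

    out = ["%VERSION  VERSION_STAMP = V0001.000  DATE = taur2"]

    def section(flag, fmt_label, lines):
        out.append(f"%FLAG {flag}")
        out.append(f"%FORMAT{fmt_label}")
        out.extend(lines)

    section("POINTERS", "(10I8)", _chunk_lines(pointers, 10, "%8d"))
    section(
        "CHARGE", "(5E16.8)",
        _chunk_lines(
            [a.charge * PRMTOP_CHARGE_SCALE for a in topology.atoms],
            5, "%16.8E",
        ),
    )
    section(
        "ATOMIC_NUMBER", "(10I8)",
        _chunk_lines(
            [_ELEMENT_TO_Z.get(a.element, 6) for a in topology.atoms],
            10, "%8d",
        ),
    )
    section(
        "MASS", "(5E16.8)",
        _chunk_lines([a.mass for a in topology.atoms], 5, "%16.8E"),
    )
    section("ATOM_NAME", "(20a4)", a4([a.name[:4] for a in topology.atoms]))
    section(
        "RESIDUE_LABEL", "(20a4)", a4([r.name[:4] for r in topology.residues])
    )
    section(
        "RESIDUE_POINTER", "(10I8)",
        _chunk_lines([r.first_atom + 1 for r in topology.residues], 10, "%8d"),
    )
    section(
        "ATOM_TYPE_INDEX", "(10I8)",
        _chunk_lines(list(range(1, n + 1)), 10, "%8d"),
    )
    section(
        "NONBONDED_PARM_INDEX", "(10I8)",
        _chunk_lines(list(nb_index), 10, "%8d"),
    )
    section(
        "LENNARD_JONES_ACOEF", "(5E16.8)", _chunk_lines(acoef, 5, "%16.8E")
    )
    section(
        "LENNARD_JONES_BCOEF", "(5E16.8)", _chunk_lines(bcoef, 5, "%16.8E")
    )
    section(
        "RADII", "(5E16.8)",
        _chunk_lines([a.born_radius for a in topology.atoms], 5, "%16.8E"),
    )
    section(
        "SCREEN", "(5E16.8)",
        _chunk_lines([a.gb_screen for a in topology.atoms], 5, "%16.8E"),
    )
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")
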