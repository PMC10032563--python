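"""Shared fixtures: tiny topologies, random sphere packs, and an
independent point-sampling surface-area oracle."""

import numpy as np
import pytest

from taur2 import ToySpec, build_toy_complex
from taur2.topology import Atom, ResidueSpan, Topology

VDW = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}


def make_topology(elements, charges=None, rmin_half=None, epsilon=None,
                  born=None, screen=None, vdw=None, names=None,
                  one_residue=False):
    """One-atom-per-residue (default) toy topology from parallel lists."""
    n = len(elements)
    charges = charges if charges is not None else [0.0] * n
    rmin_half = rmin_half if rmin_half is not None else [1.7] * n
    epsilon = epsilon if epsilon is not None else [0.1] * n
    born = born if born is not None else [1.5] * n
    screen = screen if screen is not None else [0.8] * n
    atoms = tuple(
        Atom(
            index=i,
            name=(names[i] if names else f"{el}1"),
            residue_index=0 if one_residue else i,
            element=el,
            charge=charges[i],
            lj_rmin_half=rmin_half[i],
            lj_epsilon=epsilon[i],
            born_radius=born[i],
            gb_screen=screen[i],
            vdw_radius=(vdw[i] if vdw else None),
        )
        for i, el in enumerate(elements)
    )
    if one_residue:
        residues = (ResidueSpan("TOY", 0, n - 1),)
    else:
        residues = tuple(ResidueSpan("TOY", i, i) for i in range(n))
    return Topology(atoms=atoms, residues=residues)


def random_sphere_pack(rng, n, min_dist=2.8, box_scale=3.5):
    """Non-overlapping-core random atoms with realistic vdW packing.

    The box grows whenever rejection sampling stalls, so any
    (n, min_dist) combination terminates.
    """
    edge = n ** (1 / 3) * max(box_scale, 1.4 * min_dist)
    pts = []
    attempts = 0
    while len(pts) < n:
        cand = rng.uniform(0.0, edge, 3)
        attempts += 1
        if all(np.linalg.norm(cand - p) >= min_dist for p in pts):
            pts.append(cand)
            attempts = 0
        elif attempts > 2000:
            edge *= 1.25
            attempts = 0
    elements = [str(e) for e in rng.choice(list(VDW), n)]
    top = make_topology(elements, vdw=[VDW[e] for e in elements])
    return top, np.array(pts)


def sasa_point_oracle(coords, radii, n_points=960, seed=12345):
    """Independent numerical SASA: random points on each expanded sphere.

    Uses seeded Gaussian-normalized directions, a different construction
    from the package's deterministic spiral grid.
    """
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    n = len(radii)
    areas = np.zeros(n)
    for i in range(n):
        dirs = rng.normal(size=(n_points, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        pts = coords[i] + radii[i] * dirs
        exposed = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            exposed &= ((pts - coords[j]) ** 2).sum(axis=1) > radii[j] ** 2
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * exposed.mean()
    return areas


@pytest.fixture(scope="session")
def toy_complex():
    return build_toy_complex(ToySpec(seed=1))


@pytest.fixture(scope="session")
def big_toy_complex():
    return build_toy_complex(
        ToySpec(n_receptor_atoms=125, n_ligand_atoms=6, seed=3)
    )
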