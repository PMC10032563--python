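"""Pair energies and generalized-Born solvation against closed forms
and a naive double-loop oracle."""

import numpy as np
import pytest

import taur2 as t
from taur2.constants import COULOMB_CONSTANT
from taur2.energetics import EnergeticsError, GBConfig

from conftest import make_topology


def naive_pair_energies(top, frame, group_a, group_b):
    """Independent oracle: explicit pair-by-pair double loop."""
    e_vdw = e_eel = 0.0
    for i in group_a:
        for j in group_b:
            ai, aj = top.atoms[i], top.atoms[j]
            r = float(np.linalg.norm(frame[i] - frame[j]))
            rmin = ai.lj_rmin_half + aj.lj_rmin_half
            eps = (ai.lj_epsilon * aj.lj_epsilon) ** 0.5
            e_vdw += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
            e_eel += COULOMB_CONSTANT * ai.charge * aj.charge / r
    return e_vdw, e_eel


class TestLjCoulomb:
    def test_unit_charges_at_one_angstrom(self):
        top = make_topology(["C", "C"], charges=[1.0, -1.0],
                            epsilon=[0.0, 0.0])
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        e_vdw, e_eel = t.lj_coulomb_interaction(top, frame, [0], [1])
        assert e_vdw == 0.0
        assert e_eel == pytest.approx(-COULOMB_CONSTANT, rel=1e-12)

    def test_lj_minimum_depth(self):
        top = make_topology(["C", "C"], rmin_half=[1.0, 1.0],
                            epsilon=[0.2, 0.2])
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        e_vdw, e_eel = t.lj_coulomb_interaction(top, frame, [0], [1])
        assert e_vdw == pytest.approx(-0.2, rel=1e-12)
        assert e_eel == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        top = make_topology(
            ["C", "N", "O", "S", "C", "N"],
            charges=list(rng.uniform(-1, 1, 6)),
            rmin_half=list(rng.uniform(1.2, 2.0, 6)),
            epsilon=list(rng.uniform(0.02, 0.3, 6)),
        )
        frame = rng.uniform(0, 8, (6, 3))
        a, b = [0, 1, 2], [3, 4, 5]
        got = t.lj_coulomb_interaction(top, frame, a, b)
        want = naive_pair_energies(top, frame, a, b)
        assert got[0] == pytest.approx(want[0], rel=1e-9)
        assert got[1] == pytest.approx(want[1], rel=1e-9)

    def test_symmetric_and_additive_over_partitions(self):
        rng = np.random.default_rng(3)
        top = make_topology(
            ["C"] * 6,
            charges=list(rng.uniform(-1, 1, 6)),
            rmin_half=list(rng.uniform(1.2, 2.0, 6)),
            epsilon=list(rng.uniform(0.02, 0.3, 6)),
        )
        frame = rng.uniform(0, 8, (6, 3))
        ab = t.lj_coulomb_interaction(top, frame, [0, 1], [2, 3, 4, 5])
        ba = t.lj_coulomb_interaction(top, frame, [2, 3, 4, 5], [0, 1])
        assert ab == pytest.approx(ba, rel=1e-12)
        part1 = t.lj_coulomb_interaction(top, frame, [0, 1], [2, 3])
        part2 = t.lj_coulomb_interaction(top, frame, [0, 1], [4, 5])
        assert ab[0] == pytest.approx(part1[0] + part2[0], rel=1e-12)
        assert ab[1] == pytest.approx(part1[1] + part2[1], rel=1e-12)

    def test_overlapping_atoms_rejected(self):
        top = make_topology(["C", "C"])
        frame = np.zeros((2, 3))
        with pytest.raises(EnergeticsError, match="overlap"):
            t.lj_coulomb_interaction(top, frame, [0], [1])

    def test_overlapping_groups_rejected(self):
        top = make_topology(["C", "C"])
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(EnergeticsError):
            t.lj_coulomb_interaction(top, frame, [0, 1], [1])


class TestGeneralizedBorn:
    def test_single_ion_born_closed_form(self):
        top = make_topology(["C"], charges=[1.0], born=[1.5])
        e = t.gb_polar_energy(top, np.zeros((1, 3)), [0])
        want = -0.5 * COULOMB_CONSTANT * (1 - 1 / 78.5) / 1.5
        assert e == pytest.approx(want, rel=1e-9)

    def test_large_separation_limit(self):
        top = make_topology(["C", "C"], charges=[1.0, 1.0], born=[1.5, 2.0])
        frame = np.array([[0.0, 0, 0], [500.0, 0, 0]])
        e = t.gb_polar_energy(top, frame, [0, 1])
        tau = 1 - 1 / 78.5
        want = (-0.5 * COULOMB_CONSTANT * tau * (1 / 1.5 + 1 / 2.0)
                - COULOMB_CONSTANT * tau / 500.0)
        assert e == pytest.approx(want, rel=1e-3)

    def test_zero_charges_give_zero(self):
        top = make_topology(["C"] * 4)
        frame = np.random.default_rng(0).uniform(0, 5, (4, 3))
        assert t.gb_polar_energy(top, frame, range(4)) == 0.0

    @pytest.mark.parametrize("lam", [0.5, 2.0, -1.0])
    def test_quadratic_charge_scaling(self, lam):
        rng = np.random.default_rng(5)
        charges = list(rng.uniform(-1, 1, 5))
        frame = rng.uniform(0, 6, (5, 3))
        top1 = make_topology(["C"] * 5, charges=charges)
        top2 = make_topology(["C"] * 5, charges=[lam * q for q in charges])
        e1 = t.gb_polar_energy(top1, frame, range(5))
        e2 = t.gb_polar_energy(top2, frame, range(5))
        assert e2 == pytest.approx(lam ** 2 * e1, rel=1e-9)

    def test_lone_atom_effective_radius_is_intrinsic(self):
        reff = t.gb_effective_radii(np.array([1.5]), np.array([0.8]),
                                    np.zeros((1, 3)))
        assert reff[0] == pytest.approx(1.5, rel=1e-12)

    def test_descreening_shrinks_effective_radius(self):
        # a close neighbor displaces solvent, lowering the effective radius
        reff = t.gb_effective_radii(
            np.array([1.5, 1.5]), np.array([0.8, 0.8]),
            np.array([[0.0, 0, 0], [3.0, 0, 0]]),
        )
        assert reff[0] > 1.5  # effective radius grows when solvent is displaced
        lone = t.gb_effective_radii(np.array([1.5]), np.array([0.8]),
                                    np.zeros((1, 3)))[0]
        assert reff[0] > lone


class TestNonpolar:
    @pytest.mark.parametrize("area,gamma,beta,want", [
        (1000.0, 0.0072, 0.0, 7.2),
        (0.0, 0.0072, 0.5, 0.5),
        (2000.0, 0.005, 0.92, 10.92),
    ])
    def test_linear_form(self, area, gamma, beta, want):
        assert t.nonpolar_energy(area, gamma, beta) == pytest.approx(want)

    def test_negative_area_rejected(self):
        with pytest.raises(EnergeticsError):
            t.nonpolar_energy(-1.0)
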