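"""Topology containers, parm7-subset and multi-model PDB round trips."""

import numpy as np
import pytest

import taur2 as t
from taur2.prmtop import PrmtopFormatError
from taur2.pdbio import PdbFormatError
from taur2.topology import ConsistencyError, TopologyError

from conftest import make_topology


def minimal_prmtop(charge=18.2223, acoef=409.6, bcoef=12.8,
                   drop_flag=None, natom_claim=1):
    """Hand-built single-atom parm7 text."""
    pointers = [0] * 31
    pointers[0] = natom_claim
    pointers[1] = 1
    pointers[11] = 1
    sections = [
        ("POINTERS", "(10I8)",
         ["".join(f"{p:8d}" for p in pointers[:10]),
          "".join(f"{p:8d}" for p in pointers[10:20]),
          "".join(f"{p:8d}" for p in pointers[20:30]),
          f"{pointers[30]:8d}"]),
        ("CHARGE", "(5E16.8)", [f"{charge:16.8E}"]),
        ("ATOM_NAME", "(20a4)", ["C1  "]),
        ("RESIDUE_LABEL", "(20a4)", ["LIG "]),
        ("RESIDUE_POINTER", "(10I8)", [f"{1:8d}"]),
        ("ATOM_TYPE_INDEX", "(10I8)", [f"{1:8d}"]),
        ("NONBONDED_PARM_INDEX", "(10I8)", [f"{1:8d}"]),
        ("LENNARD_JONES_ACOEF", "(5E16.8)", [f"{acoef:16.8E}"]),
        ("LENNARD_JONES_BCOEF", "(5E16.8)", [f"{bcoef:16.8E}"]),
        ("RADII", "(5E16.8)", [f"{1.5:16.8E}"]),
        ("SCREEN", "(5E16.8)", [f"{0.8:16.8E}"]),
    ]
    lines = ["%VERSION  VERSION_STAMP = V0001.000"]
    for flag, fmt, body in sections:
        if flag == drop_flag:
            continue
        lines += [f"%FLAG {flag}", f"%FORMAT{fmt}"] + body
    return "\n".join(lines) + "\n"


class TestPrmtopReader:
    def test_charge_unit_conversion(self, tmp_path):
        p = tmp_path / "one.prmtop"
        p.write_text(minimal_prmtop(charge=18.2223))
        top = t.read_prmtop_subset(p)
        assert top.n_atoms == 1
        assert top.atoms[0].charge == pytest.approx(1.0, abs=1e-9)

    def test_lj_coefficient_inversion(self, tmp_path):
        # A = eps*rmin^12, B = 2*eps*rmin^6 with rmin = 2 A, eps = 0.1
        p = tmp_path / "lj.prmtop"
        p.write_text(minimal_prmtop(acoef=0.1 * 2.0 ** 12,
                                    bcoef=2 * 0.1 * 2.0 ** 6))
        atom = t.read_prmtop_subset(p).atoms[0]
        assert atom.lj_rmin_half == pytest.approx(1.0, rel=1e-9)
        assert atom.lj_epsilon == pytest.approx(0.1, rel=1e-9)

    def test_missing_flag_names_it(self, tmp_path):
        p = tmp_path / "bad.prmtop"
        p.write_text(minimal_prmtop(drop_flag="RADII"))
        with pytest.raises(PrmtopFormatError, match="RADII"):
            t.read_prmtop_subset(p)

    def test_count_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad2.prmtop"
        p.write_text(minimal_prmtop(natom_claim=2))
        with pytest.raises(ConsistencyError):
            t.read_prmtop_subset(p)

    def test_roundtrip_preserves_parameters(self, tmp_path, toy_complex):
        top, _ = toy_complex
        p = tmp_path / "toy.prmtop"
        t.write_prmtop_subset(top, p)
        back = t.read_prmtop_subset(p)
        assert back.n_atoms == top.n_atoms
        assert back.n_residues == top.n_residues
        for a, b in zip(top.atoms, back.atoms):
            assert a.name == b.name
            assert a.element == b.element
            assert a.residue_index == b.residue_index
            assert b.charge == pytest.approx(a.charge, abs=1e-7)
            assert b.lj_rmin_half == pytest.approx(a.lj_rmin_half, rel=1e-6)
            assert b.lj_epsilon == pytest.approx(a.lj_epsilon, rel=1e-6)
            assert b.born_radius == pytest.approx(a.born_radius, rel=1e-7)
            assert b.gb_screen == pytest.approx(a.gb_screen, rel=1e-7)


class TestYamlTopology:
    def test_roundtrip(self, tmp_path, toy_complex):
        top, _ = toy_complex
        p = tmp_path / "toy.yaml"
        t.write_topology_yaml(top, p)
        back = t.read_topology_yaml(p)
        assert back == top


class TestMultimodelPdb:
    def test_three_models_five_atoms(self, tmp_path):
        top = make_topology(["C"] * 5)
        coords = np.arange(45, dtype=float).reshape(3, 5, 3)
        traj = t.Trajectory(coords, [0.0, 10.0, 20.0], top)
        p = tmp_path / "t.pdb"
        t.write_multimodel_pdb(traj, p)
        back = t.read_multimodel_pdb(p, top)
        assert back.n_frames == 3
        assert back.coordinates.shape == (3, 5, 3)

    def test_coordinate_roundtrip_at_format_precision(self, tmp_path,
                                                      toy_complex):
        top, pose = toy_complex
        traj = t.sample_harmonic_ensemble(top, pose, 0.3, 4, seed=9)
        p = tmp_path / "t.pdb"
        t.write_multimodel_pdb(traj, p)
        back = t.read_multimodel_pdb(p, top)
        assert np.abs(back.coordinates - traj.coordinates).max() <= 1e-3

    def test_ragged_model_names_frame(self, tmp_path):
        top = make_topology(["C"] * 3)
        traj = t.Trajectory(np.zeros((2, 3, 3)) + np.arange(2)[:, None, None],
                            [0.0, 10.0], top)
        p = tmp_path / "t.pdb"
        t.write_multimodel_pdb(traj, p)
        lines = p.read_text().splitlines()
        # drop one ATOM line from the second model
        atom_lines = [i for i, l in enumerate(lines) if l.startswith("ATOM")]
        del lines[atom_lines[-1]]
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(PdbFormatError, match="frame 1"):
            t.read_multimodel_pdb(p, top)


class TestPartition:
    def test_selects_exactly_named_residues(self):
        top = make_topology(["C"] * 5)
        sel = t.select_partition(top, range(3, 5))
        assert sel.ligand_atoms == {3, 4}
        assert sel.receptor_atoms == {0, 1, 2}

    def test_covering_selection_rejected(self):
        top = make_topology(["C"] * 5)
        with pytest.raises(TopologyError):
            t.select_partition(top, range(0, 5))

    def test_empty_selection_rejected(self):
        top = make_topology(["C"] * 5)
        with pytest.raises(TopologyError):
            t.select_partition(top, [])

    @pytest.mark.parametrize("residues", [[0], [1, 3], [4], [0, 2, 4]])
    def test_partition_is_disjoint_cover(self, residues):
        top = make_topology(["C", "N", "O", "S", "C", "N"])
        sel = t.select_partition(top, residues)
        assert not (sel.ligand_atoms & sel.receptor_atoms)
        assert sel.ligand_atoms | sel.receptor_atoms == set(range(6))
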