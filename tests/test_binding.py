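"""MM-GBSA assembly: frame Delta-terms, replica aggregation,
per-residue decomposition and RMSF."""

import numpy as np
import pytest

import taur2 as t
from taur2.binding import MeanSpread, assemble_components
from taur2.constants import COULOMB_CONSTANT
from taur2.energetics import FrameEnergies, GBConfig
from taur2.entropy import EntropyTerm

from conftest import make_topology


def frame_list(values):
    """FrameEnergies with constant Delta-terms (vdw, eel, pol, np)."""
    return [FrameEnergies(*values, frame_index=i) for i in range(2)]


class TestMmgbsaFrame:
    def test_vdw_eel_reduce_to_intergroup_pair_sums(self, toy_complex):
        top, pose = toy_complex
        fe = t.mmgbsa_frame(top, pose)
        e_vdw, e_eel = t.lj_coulomb_interaction(
            top, pose, top.ligand_atoms, top.receptor_atoms
        )
        assert fe.e_vdw == pytest.approx(e_vdw, rel=1e-12)
        assert fe.e_eel == pytest.approx(e_eel, rel=1e-12)

    def test_noninteracting_limit(self, toy_complex):
        top, pose = toy_complex
        far = pose.copy()
        far[top.ligand_indices] += np.array([200.0, 0.0, 0.0])
        fe = t.mmgbsa_frame(top, far)
        for term in (fe.e_vdw, fe.e_eel, fe.g_polar, fe.g_nonpolar):
            assert abs(term) < 0.05

    def test_two_ion_gb_closed_form(self):
        # screen = 0 disables descreening, so effective radii stay
        # intrinsic and the Delta reduces to the screened cross term
        top = make_topology(["C", "C"], charges=[1.0, -1.0],
                            born=[1.5, 2.0], screen=[0.0, 0.0],
                            epsilon=[0.0, 0.0])
        from dataclasses import replace
        top = replace(top, ligand_atoms=frozenset({1}),
                      receptor_atoms=frozenset({0}))
        r = 4.0
        frame = np.array([[0.0, 0, 0], [r, 0, 0]])
        fe = t.mmgbsa_frame(top, frame)
        rirj = 1.5 * 2.0
        fgb = np.sqrt(r ** 2 + rirj * np.exp(-r ** 2 / (4 * rirj)))
        tau = 1 - 1 / 78.5
        want = -COULOMB_CONSTANT * tau * (1.0 * -1.0) / fgb
        assert fe.g_polar == pytest.approx(want, rel=1e-9)


class TestAggregateReplicas:
    @pytest.mark.parametrize("components,tds,want", [
        ((-110.3, -2158.4, 2200.7, -16.7), -44.8, -39.9),
        ((-120.2, -214.2, 306.0, -17.5), -44.4, -1.5),
    ])
    def test_reported_component_assembly(self, components, tds, want):
        res = t.aggregate_replicas(
            [frame_list(components)],
            EntropyTerm(tds, "wsas", 2),
            discard=0.0,
        )
        assert res.dg_bind.mean == pytest.approx(want, abs=1e-9)

    def test_single_replica_constant_frames(self):
        res = t.aggregate_replicas(
            [frame_list((-1.0, -2.0, 3.0, -0.5))], None, discard=0.0
        )
        assert res.dg_bind == MeanSpread(pytest.approx(-0.5), 0.0)
        assert res.de_vdw.spread == 0.0
        assert res.n_replicas == 1

    def test_additivity_invariant_exact(self):
        rng = np.random.default_rng(0)
        reps = []
        for _ in range(5):
            reps.append([
                FrameEnergies(*rng.normal(0, 30, 4), frame_index=i)
                for i in range(8)
            ])
        entropy = [EntropyTerm(float(v), "interaction", 8)
                   for v in rng.normal(-40, 2, 5)]
        res = t.aggregate_replicas(reps, entropy, discard=0.25)
        want = (res.de_vdw.mean + res.de_eel.mean + res.dg_polar.mean
                + res.dg_nonpolar.mean - res.t_delta_s.mean)
        assert res.dg_bind.mean == pytest.approx(want, abs=1e-9)

    def test_permutation_invariance_over_replicas(self):
        rng = np.random.default_rng(1)
        reps = [
            [FrameEnergies(*rng.normal(0, 10, 4), frame_index=i)
             for i in range(6)]
            for _ in range(4)
        ]
        a = t.aggregate_replicas(reps, None, discard=0.0)
        b = t.aggregate_replicas(reps[::-1], None, discard=0.0)
        assert a.dg_bind.mean == pytest.approx(b.dg_bind.mean, rel=1e-12)
        assert a.dg_bind.spread == pytest.approx(b.dg_bind.spread, rel=1e-12)

    def test_discard_window_must_leave_frames(self):
        with pytest.raises(ValueError):
            t.aggregate_replicas([frame_list((0, 0, 0, 0))], None, discard=2)

    def test_assemble_components_sum(self):
        assert assemble_components(-110.3, -2158.4, 2200.7, -16.7, -44.8) \
            == pytest.approx(-39.9, abs=1e-9)


class TestDecomposition:
    def test_pairwise_parts_sum_to_intergroup_totals(self, toy_complex):
        top, pose = toy_complex
        traj = t.sample_harmonic_ensemble(top, pose, 0.3, 4, seed=2)
        contribs = t.per_residue_decomposition(top, traj)
        tot_vdw = sum(c.e_vdw for c in contribs)
        tot_eel = sum(c.e_eel for c in contribs)
        want = np.mean([
            t.lj_coulomb_interaction(top, traj.coordinates[f],
                                     top.ligand_atoms, top.receptor_atoms)
            for f in range(traj.n_frames)
        ], axis=0)
        assert tot_vdw == pytest.approx(want[0], abs=1e-6)
        assert tot_eel == pytest.approx(want[1], abs=1e-6)

    def test_distant_residue_contributes_nothing(self, toy_complex):
        top, pose = toy_complex
        far = pose.copy()
        last_res = top.ligand_residues()[-1]
        far[top.residue_atoms(last_res)] += np.array([200.0, 0.0, 0.0])
        traj = t.Trajectory(far[None], [0.0], top)
        contribs = {c.residue_index: c
                    for c in t.per_residue_decomposition(top, traj)}
        assert abs(contribs[last_res].energy) < 0.05
        assert contribs[last_res].mean_min_distance > 150.0

    def test_charged_residue_dominates_electrostatics(self):
        # ligand residue 1 charged, residue 2 neutral, charged receptor
        top = make_topology(
            ["C", "C", "C"], charges=[1.0, -0.8, 0.0],
            epsilon=[0.0] * 3,
        )
        from dataclasses import replace
        top = replace(top, ligand_atoms=frozenset({1, 2}),
                      receptor_atoms=frozenset({0}))
        frame = np.array([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]])
        traj = t.Trajectory(frame[None], [0.0], top)
        contribs = {c.residue_index: c
                    for c in t.per_residue_decomposition(top, traj)}
        assert abs(contribs[1].e_eel) > abs(contribs[2].e_eel)


class TestRmsf:
    def test_static_trajectory_is_zero(self, toy_complex):
        top, pose = toy_complex
        traj = t.sample_harmonic_ensemble(top, pose, 0.0, 3, seed=0)
        assert np.allclose(t.residue_rmsf(traj), 0.0, atol=1e-10)

    def test_rigid_translation_removed_by_fit(self, toy_complex):
        top, pose = toy_complex
        coords = np.stack([pose + np.array([d, 2 * d, -d])
                           for d in (0.0, 3.0, 7.0)])
        traj = t.Trajectory(coords, [0.0, 10.0, 20.0], top)
        assert np.allclose(t.residue_rmsf(traj), 0.0, atol=1e-8)

    def test_isotropic_jitter_chi_distribution_value(self, big_toy_complex):
        # RMSF of sigma-jittered coordinates is sqrt(3)*sigma; fit noise
        # is negligible for a large receptor
        top, pose = big_toy_complex
        traj = t.sample_harmonic_ensemble(top, pose, 0.5, 2000, seed=11)
        rmsf = t.residue_rmsf(traj, group=top.receptor_atoms)
        lig_res = top.ligand_residues()
        want = np.sqrt(3) * 0.5
        assert rmsf[lig_res] == pytest.approx(want, rel=0.05)

    def test_degenerate_fit_rejected(self):
        top = make_topology(["C", "C"])
        coords = np.zeros((2, 2, 3))
        coords[:, 1, 0] = [3.0, 3.0]
        traj = t.Trajectory(coords, [0.0, 10.0], top)
        with pytest.raises(ValueError):
            t.residue_rmsf(traj, group=[0, 1])
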