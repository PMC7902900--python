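"""Molecular-mechanics pair energies, the nonpolar term, and the MM/PBSA
binding ledger with its per-residue decomposition."""

import numpy as np
import pytest

import mdpost as mp
from mdpost.energetics import GAMMA_NONPOLAR, B_NONPOLAR, mm_pair_energy_matrix
from mdpost.errors import ParameterError, SelectionError, SingularityError
from mdpost.pbsolver import COULOMB_K
from mdpost.topology import AtomSelection


def pair_system(charges, sigma=None, epsilon=None):
    n = len(charges)
    spec = mp.SyntheticSpec(
        chain_layout=[("A", 1), ("B", n - 1)],
        n_residues=n,
        charges=np.asarray(charges, float),
        lj_sigma=None if sigma is None else np.asarray(sigma, float),
        lj_epsilon=None if epsilon is None else np.asarray(epsilon, float),
        seed=0,
    )
    return mp.build_toy_system(spec)


class TestMmPairEnergy:
    def test_coulomb_hand_value(self):
        # +1/-1 at r chosen so k/r = 100 exactly
        top = pair_system([1.0, -1.0])
        r = COULOMB_K / 100.0
        frame = np.array([[0.0, 0, 0], [r, 0, 0]])
        a = AtomSelection(np.array([0]), "a")
        b = AtomSelection(np.array([1]), "b")
        e_vdw, e_ele = mp.mm_pair_energy(frame, top, a, b)
        assert e_ele == pytest.approx(-100.0, abs=1e-10)

    def test_lj_zero_at_sigma_and_minimum_at_r_min(self):
        top = pair_system([0.0, 0.0], sigma=[3.4, 3.4], epsilon=[0.1, 0.1])
        a = AtomSelection(np.array([0]), "a")
        b = AtomSelection(np.array([1]), "b")
        frame = np.array([[0.0, 0, 0], [3.4, 0, 0]])
        e_vdw, _ = mp.mm_pair_energy(frame, top, a, b)
        assert e_vdw == pytest.approx(0.0, abs=1e-12)
        frame = np.array([[0.0, 0, 0], [2 ** (1 / 6) * 3.4, 0, 0]])
        e_vdw, _ = mp.mm_pair_energy(frame, top, a, b)
        assert e_vdw == pytest.approx(-0.1, abs=1e-12)

    def test_lorentz_berthelot_combining(self):
        top = pair_system([0.0, 0.0], sigma=[3.0, 4.0], epsilon=[0.1, 0.4])
        a = AtomSelection(np.array([0]), "a")
        b = AtomSelection(np.array([1]), "b")
        sig_ij, eps_ij = 3.5, 0.2
        frame = np.array([[0.0, 0, 0], [sig_ij, 0, 0]])
        e_vdw, _ = mp.mm_pair_energy(frame, top, a, b)
        assert e_vdw == pytest.approx(0.0, abs=1e-12)
        frame = np.array([[0.0, 0, 0], [2 ** (1 / 6) * sig_ij, 0, 0]])
        e_vdw, _ = mp.mm_pair_energy(frame, top, a, b)
        assert e_vdw == pytest.approx(-eps_ij, abs=1e-12)

    def test_overlapping_atoms_raise_singularity(self):
        top = pair_system([1.0, 1.0])
        frame = np.zeros((2, 3))
        with pytest.raises(SingularityError):
            mp.mm_pair_energy(
                frame, top,
                AtomSelection(np.array([0]), "a"),
                AtomSelection(np.array([1]), "b"),
            )

    def test_overlapping_groups_rejected(self, toy_complex):
        sel = toy_complex.topology.select("chain A")
        with pytest.raises(SelectionError):
            mp.mm_pair_energy(toy_complex.coords[0], toy_complex.topology, sel, sel)


class TestNonpolar:
    def test_zero_sasa_gives_b(self):
        assert mp.nonpolar_energy(0.0) == 0.92

    def test_thousand_square_angstroms(self):
        assert mp.nonpolar_energy(1000.0) == pytest.approx(6.34)

    def test_zero_gamma_gives_b_regardless(self):
        assert mp.nonpolar_energy(12345.0, gamma=0.0) == B_NONPOLAR

    def test_negative_sasa_rejected(self):
        with pytest.raises(ParameterError):
            mp.nonpolar_energy(-1.0)


PB_FAST = mp.PBGridSpec(spacing=0.6, padding=6.0)


class TestMmpbsaBinding:
    def test_internal_energy_identically_zero(self, toy_complex):
        rec = toy_complex.topology.select("chain A")
        lig = toy_complex.topology.select("chain B")
        report = mp.mmpbsa_binding(toy_complex, rec, lig, PB_FAST, frame_stride=1,
                                   sasa_points=240)
        assert np.all(report.breakdown.e_int == 0.0)

    def test_gbinding_identity(self, toy_complex):
        rec = toy_complex.topology.select("chain A")
        lig = toy_complex.topology.select("chain B")
        report = mp.mmpbsa_binding(toy_complex, rec, lig, PB_FAST, frame_stride=1,
                                   sasa_points=240)
        b = report.breakdown
        assert np.abs(b.g_binding - (b.e_mm + b.g_solv)).max() <= 1e-10
        assert np.abs(b.e_mm - (b.e_vdw + b.e_ele + b.e_int)).max() <= 1e-12

    def test_components_match_hand_assembly(self, toy_complex):
        rec = toy_complex.topology.select("chain A")
        lig = toy_complex.topology.select("chain B")
        report = mp.mmpbsa_binding(toy_complex, rec, lig, PB_FAST, frame_stride=1,
                                   sasa_points=240)
        frame = toy_complex.coords[0]
        top = toy_complex.topology
        e_vdw, e_ele = mp.mm_pair_energy(frame, top, rec, lig)
        assert report.breakdown.e_vdw[0] == pytest.approx(e_vdw, abs=1e-6)
        assert report.breakdown.e_ele[0] == pytest.approx(e_ele, abs=1e-6)

        from mdpost.topology import subset_topology
        from mdpost.sasa import shrake_rupley_sasa

        pb_c = mp.solve_pb(frame, top, PB_FAST)
        rec_top = subset_topology(top, rec.indices)
        lig_top = subset_topology(top, lig.indices)
        pb_r = mp.solve_pb(frame[rec.indices], rec_top, PB_FAST)
        pb_l = mp.solve_pb(frame[lig.indices], lig_top, PB_FAST)
        assert report.breakdown.e_pb[0] == pytest.approx(pb_c - pb_r - pb_l, abs=1e-6)

        s_c = shrake_rupley_sasa(frame, top, n_points=240).total
        s_r = shrake_rupley_sasa(frame[rec.indices], rec_top, n_points=240).total
        s_l = shrake_rupley_sasa(frame[lig.indices], lig_top, n_points=240).total
        expected_np = (
            mp.nonpolar_energy(s_c) - mp.nonpolar_energy(s_r)
            - mp.nonpolar_energy(s_l)
        )
        assert report.breakdown.e_nonpolar[0] == pytest.approx(expected_np, abs=1e-9)

    def test_receptor_ligand_swap_leaves_gbinding(self, toy_complex):
        rec = toy_complex.topology.select("chain A")
        lig = toy_complex.topology.select("chain B")
        r1 = mp.mmpbsa_binding(toy_complex, rec, lig, PB_FAST, frame_stride=1,
                               sasa_points=240)
        r2 = mp.mmpbsa_binding(toy_complex, lig, rec, PB_FAST, frame_stride=1,
                               sasa_points=240)
        assert r1.mean("dG_binding") == pytest.approx(
            r2.mean("dG_binding"), abs=1e-9
        )

    def test_distant_ligand_components_vanish(self):
        spec = mp.SyntheticSpec(
            chain_layout=[("A", 2), ("B", 1)], n_residues=3,
            charges=np.array([0.5, -0.5, 0.3]), seed=0,
        )
        top = mp.build_toy_system(spec)
        coords = np.array([[[0.0, 0, 0], [4.0, 0, 0], [2.0, 60.0, 0]]])
        traj = mp.Trajectory(top, coords)
        rec = top.select("chain A")
        lig = top.select("chain B")
        report = mp.mmpbsa_binding(traj, rec, lig, PB_FAST, frame_stride=1,
                                   sasa_points=240)
        assert abs(report.breakdown.e_vdw[0]) <= 1e-3
        assert abs(report.breakdown.e_ele[0]) <= 1e-2  # monopole tail ~ q1q2/r
        # the nonpolar model gamma*SASA + b keeps its constant -b offset even
        # for a fully separated pair; everything else vanishes
        assert report.mean("dG_binding") + B_NONPOLAR == pytest.approx(0.0, abs=0.05)

    def test_translation_invariance_exact(self, toy_complex):
        # all components depend on relative geometry only; the PB grid is
        # anchored to the solute bounding box, so it moves rigidly with it
        rec = toy_complex.topology.select("chain A")
        lig = toy_complex.topology.select("chain B")
        base = mp.mmpbsa_binding(toy_complex, rec, lig, PB_FAST, frame_stride=1,
                                 sasa_points=240)
        moved = toy_complex.coords[0] + np.array([7.0, -3.0, 11.0])
        traj2 = mp.Trajectory(toy_complex.topology, moved[None])
        other = mp.mmpbsa_binding(traj2, rec, lig, PB_FAST, frame_stride=1,
                                  sasa_points=240)
        for comp in ("dE_vdw", "dE_ele", "dE_nonpolar", "dE_PB", "dG_binding"):
            assert base.mean(comp) == pytest.approx(other.mean(comp), abs=1e-6)

    def test_rotation_invariance_to_quadrature_resolution(self, toy_complex):
        # MM terms are exactly rotation invariant; SASA and the re-gridded PB
        # term agree to the quadrature/grid discretisation level
        rec = toy_complex.topology.select("chain A")
        lig = toy_complex.topology.select("chain B")
        base = mp.mmpbsa_binding(toy_complex, rec, lig, PB_FAST, frame_stride=1,
                                 sasa_points=960)
        rot = np.array([[0.0, -1, 0], [1.0, 0, 0], [0, 0, 1.0]])  # 90° about z
        traj2 = mp.Trajectory(
            toy_complex.topology, (toy_complex.coords[0] @ rot.T)[None]
        )
        other = mp.mmpbsa_binding(traj2, rec, lig, PB_FAST, frame_stride=1,
                                  sasa_points=960)
        for comp in ("dE_vdw", "dE_ele"):
            assert base.mean(comp) == pytest.approx(other.mean(comp), abs=1e-6)
        assert base.mean("dE_nonpolar") == pytest.approx(
            other.mean("dE_nonpolar"), abs=0.01
        )
        assert base.mean("dE_PB") == pytest.approx(other.mean("dE_PB"), abs=0.05)


class TestPerResidueDecomposition:
    def test_residue_sums_reproduce_totals(self, toy_complex):
        rec = toy_complex.topology.select("chain A")
        lig = toy_complex.topology.select("chain B")
        report = mp.mmpbsa_binding(toy_complex, rec, lig, PB_FAST, frame_stride=1,
                                   sasa_points=240)
        df = mp.per_residue_decomposition(toy_complex, rec, lig, PB_FAST,
                                          frame_stride=1, sasa_points=240)
        b = report.breakdown
        assert df["dE_vdw"].sum() == pytest.approx(b.e_vdw.mean(), abs=1e-6)
        assert df["dE_ele"].sum() == pytest.approx(b.e_ele.mean(), abs=1e-6)
        assert df["dE_polar"].sum() == pytest.approx(b.e_pb.mean(), abs=1e-6)
        assert df["dE_nonpolar"].sum() == pytest.approx(
            b.e_nonpolar.mean(), abs=1e-6
        )

    def test_single_residue_ligand_row_carries_half_cross_term(self, toy_complex):
        rec = toy_complex.topology.select("chain A")
        lig = toy_complex.topology.select("chain B")
        df = mp.per_residue_decomposition(toy_complex, rec, lig, PB_FAST,
                                          frame_stride=1, sasa_points=240)
        frame = toy_complex.coords[0]
        e_vdw, e_ele = mp.mm_pair_energy(frame, toy_complex.topology, rec, lig)
        row = df[df["chain"] == "B"].iloc[0]
        assert row["dE_vdw"] == pytest.approx(0.5 * e_vdw, abs=1e-10)
        assert row["dE_ele"] == pytest.approx(0.5 * e_ele, abs=1e-10)

    def test_neutral_residue_carries_no_electrostatics(self):
        spec = mp.SyntheticSpec(
            chain_layout=[("A", 2), ("B", 1)], n_residues=3,
            charges=np.array([1.0, 0.0, -1.0]), seed=0,
        )
        top = mp.build_toy_system(spec)
        coords = np.array([[[0.0, 0, 0], [4.0, 0, 0], [2.0, 4.0, 0]]])
        traj = mp.Trajectory(top, coords)
        vdw, ele = mm_pair_energy_matrix(
            coords[0], top, top.select("chain A"), top.select("chain B")
        )
        assert ele[1, 0] == 0.0  # the neutral atom contributes nothing
        df = mp.per_residue_decomposition(
            traj, top.select("chain A"), top.select("chain B"), PB_FAST,
            frame_stride=1, sasa_points=240,
        )
        charged = df[(df["chain"] == "A") & (df["resid"] == 1)].iloc[0]
        neutral = df[(df["chain"] == "A") & (df["resid"] == 2)].iloc[0]
        total_ele = df["dE_ele"].sum()
        assert neutral["dE_ele"] == 0.0
        assert charged["dE_ele"] + df[df["chain"] == "B"]["dE_ele"].sum() == (
            pytest.approx(total_ele, abs=1e-12)
        )
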