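"""End-point binding free energy assembly, decomposition, truncation, entropy."""

import numpy as np
import pytest

from bfekit.core import Bond, MolecularSystem, Trajectory
from bfekit.endpoint import (delta_delta_g, endpoint_bfe,
                             per_residue_decomposition, truncate_for_entropy)
from bfekit.mm import interaction_energy
from bfekit.nma import nma_entropy, vibrational_entropy
from bfekit.solvation import (SolvationConfig, gb_energy, lcpo_sasa,
                              nonpolar_energy)
from bfekit.synth import make_toy_complex

from conftest import make_atom


@pytest.fixture
def toy():
    system, frame, _ = make_toy_complex(seed=11)
    return system, Trajectory(frame[None])


class TestEndpoint:
    def test_noninteracting_neutral_ligand(self):
        atoms = [make_atom(0, "L1", "C", resid=1, charge=0.0, eps=0.0),
                 make_atom(1, "CA", "C", resid=2, charge=0.3),
                 make_atom(2, "CB", "C", resid=2, charge=-0.3)]
        s = MolecularSystem(atoms, bonds=[Bond(1, 2, 300.0, 1.5)],
                            ligand_mask=[0], receptor_mask=[1, 2])
        f = np.array([[200.0, 0, 0], [0, 0, 0], [1.5, 0, 0]])
        res = endpoint_bfe(s, Trajectory(f[None]))
        assert res.mean["e_ele"] == 0.0
        assert res.mean["e_vdw"] == pytest.approx(0.0, abs=1e-9)
        # ligand far away: its GB radii are unperturbed, dG_GB ~ 0
        assert res.mean["g_polar"] == pytest.approx(0.0, abs=1e-3)

    def test_single_frame_matches_cross_module_composition(self, toy):
        system, traj = toy
        frame = traj.frames[0]
        cfg = SolvationConfig()
        res = endpoint_bfe(system, traj, cfg)
        rec = system.subset(system.receptor_mask)
        lig = system.subset(system.ligand_mask)
        ri, li = sorted(system.receptor_mask), sorted(system.ligand_mask)
        ele, vdw = interaction_energy(system, frame)
        g_pol = (gb_energy(system, frame, cfg) - gb_energy(rec, frame[ri], cfg)
                 - gb_energy(lig, frame[li], cfg))
        g_sa = (nonpolar_energy(lcpo_sasa(system, frame))
                - nonpolar_energy(lcpo_sasa(rec, frame[ri]))
                - nonpolar_energy(lcpo_sasa(lig, frame[li])))
        assert res.dh == pytest.approx(ele + vdw + g_pol + g_sa, abs=1e-10)

    def test_bonded_terms_cancel_exactly_every_frame(self, toy):
        system, _ = toy
        frames = [toy[1].frames[0], toy[1].frames[0] * 1.03 + 0.2]
        res = endpoint_bfe(system, Trajectory(np.array(frames)))
        assert (res.per_frame["e_bonded"] == 0.0).all()

    def test_mean_permutation_invariant(self, toy):
        system, _ = toy
        base = toy[1].frames[0]
        frames = np.array([base, base + 0.05, base - 0.02])
        r1 = endpoint_bfe(system, Trajectory(frames))
        r2 = endpoint_bfe(system, Trajectory(frames[::-1]))
        assert r1.dh == pytest.approx(r2.dh, abs=1e-12)

    def test_empty_trajectory_error(self, toy):
        with pytest.raises(ValueError, match="empty"):
            endpoint_bfe(toy[0], Trajectory(np.zeros((0, toy[0].n_atoms, 3))))


class TestDecomposition:
    def test_charged_residue_carries_all_electrostatics(self):
        atoms = [make_atom(0, "L1", "C", resid=1, charge=0.5, eps=0.0),
                 make_atom(1, "CA", "C", resid=2, charge=-0.5, eps=0.0),
                 make_atom(2, "CA", "C", resid=3, charge=0.0, eps=0.0)]
        s = MolecularSystem(atoms, ligand_mask=[0], receptor_mask=[1, 2])
        f = np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 3.0, 0]])
        dec = per_residue_decomposition(s, Trajectory(f[None]))
        assert dec.loc[3, "ele"] == 0.0
        # receptor residue 2 takes half of the single cross pair
        total_ele = interaction_energy(s, f)[0]
        assert dec.loc[2, "ele"] == pytest.approx(total_ele / 2, abs=1e-12)
        assert dec.loc[1, "ele"] == pytest.approx(total_ele / 2, abs=1e-12)

    def test_residue_sums_reconstruct_totals(self, toy):
        system, traj = toy
        res = endpoint_bfe(system, traj)
        dec = per_residue_decomposition(system, traj)
        for col, tot in (("ele", "e_ele"), ("vdw", "e_vdw"),
                         ("polar", "g_polar"), ("nonpolar", "g_sa")):
            assert dec[col].sum() == pytest.approx(res.mean[tot], abs=1e-6)
        assert dec["total"].sum() == pytest.approx(res.dh, abs=1e-6)

    def test_mutant_minus_wild_table_is_hand_difference(self):
        cfg = SolvationConfig()
        s_wt, f_wt, _ = make_toy_complex(seed=5)
        s_mt, f_mt, _ = make_toy_complex(seed=5, mutate=True)
        d_wt = per_residue_decomposition(s_wt, Trajectory(f_wt[None]), cfg)
        d_mt = per_residue_decomposition(s_mt, Trajectory(f_mt[None]), cfg)
        ddg = d_mt["total"] - d_wt["total"]
        for rid in d_wt.index:
            assert ddg[rid] == pytest.approx(
                d_mt.loc[rid, "total"] - d_wt.loc[rid, "total"])
        # planted repulsion shows up at the contact residue's gas-phase
        # electrostatics (the polar solvation term screens most of it in the
        # total, as expected for a solvent-exposed charge flip)
        ddg_ele = d_mt["ele"] - d_wt["ele"]
        assert ddg_ele[1001] > 0.5
        # the other half of the planted pair change sits on the ligand row
        assert ddg_ele[1001] == pytest.approx(ddg_ele.max())
        assert ddg_ele.drop([1, 1001]).abs().max() < 1e-9


class TestTruncation:
    def _system(self, far_distance):
        atoms = [make_atom(0, "L1", "C", resid=1),
                 make_atom(1, "CA", "C", resid=1001),
                 make_atom(2, "CB", "C", resid=1001),
                 make_atom(3, "CA", "C", resid=1002)]
        s = MolecularSystem(atoms, bonds=[Bond(1, 2, 300.0, 1.5)],
                            ligand_mask=[0], receptor_mask=[1, 2, 3])
        f = np.array([[0.0, 0, 0], [4.0, 0, 0], [5.5, 0, 0],
                      [far_distance, 0, 0]])
        return s, f

    def test_identity_when_everything_close(self):
        s, f = self._system(6.0)
        sub, sub_f, info = truncate_for_entropy(s, f, cutoff=9.0)
        assert sub.n_atoms == 4
        assert info["kept_residues"] == [1001, 1002]

    def test_planted_far_residue_excluded(self):
        s, f = self._system(20.0)
        sub, sub_f, info = truncate_for_entropy(s, f, cutoff=9.0)
        assert sub.n_atoms == 3
        assert 1002 not in info["kept_residues"]

    def test_boundary_atom_pulls_whole_residue(self):
        # CB of residue 1001 at 8.99 A: entire residue kept including CA
        atoms = [make_atom(0, "L1", "C", resid=1),
                 make_atom(1, "CA", "C", resid=1001),
                 make_atom(2, "CB", "C", resid=1001)]
        s = MolecularSystem(atoms, bonds=[Bond(1, 2, 300.0, 1.5)],
                            ligand_mask=[0], receptor_mask=[1, 2])
        f = np.array([[0.0, 0, 0], [10.5, 0, 0], [8.99, 0, 0]])
        sub, _, info = truncate_for_entropy(s, f, cutoff=9.0)
        assert sub.n_atoms == 3

    def test_missing_ligand_mask_error(self):
        s = MolecularSystem([make_atom(0)])
        with pytest.raises(ValueError, match="ligand"):
            truncate_for_entropy(s, np.zeros((1, 3)))


class TestEntropy:
    def test_diatomic_matches_closed_form(self, diatomic):
        system, frame = diatomic
        rep = nma_entropy(system, frame, T=300.0)
        m1, m2 = system.masses
        mu = m1 * m2 / (m1 + m2)
        nu = np.sqrt(2 * 300.0 * 4184.0 / 1e-23 / mu) / (2 * np.pi)
        assert len(rep.frequencies_hz) == 1
        assert rep.frequencies_hz[0] == pytest.approx(nu, rel=1e-4)
        s_closed = vibrational_entropy(np.array([nu]), 300.0)
        # criterion in energy units at T
        assert 300.0 * rep.s_vib == pytest.approx(300.0 * s_closed, abs=1e-3)

    def test_entropy_increases_with_temperature(self, diatomic):
        system, frame = diatomic
        r300 = nma_entropy(system, frame, T=300.0)
        r600 = nma_entropy(system, frame, T=600.0)
        assert r600.s_vib > r300.s_vib
        assert r600.s_trans > r300.s_trans

    def test_rigid_translation_leaves_entropy_unchanged(self, diatomic):
        system, frame = diatomic
        r1 = nma_entropy(system, frame)
        r2 = nma_entropy(system, frame + np.array([10.0, -5.0, 2.0]))
        assert r1.s_total == pytest.approx(r2.s_total, abs=1e-9)


class TestDeltaDeltaG:
    def _result(self, dh):
        import pandas as pd
        from bfekit.endpoint import EndpointResult
        df = pd.DataFrame({"e_ele": [0.0], "e_vdw": [0.0], "e_bonded": [0.0],
                           "g_polar": [0.0], "g_sa": [0.0], "dh": [dh]})
        return EndpointResult("GB", 1.0, 1, df)

    def test_identical_results_zero(self):
        assert delta_delta_g(self._result(-9.0), self._result(-9.0)) == 0.0

    def test_sign_convention_resistance_positive(self):
        assert delta_delta_g(self._result(-8.0), self._result(-10.0)) == 2.0

    def test_repeat_bookkeeping_mean_and_sd(self):
        # three independent repeats of a mutant/wild pair with binding
        # attenuations typical of a far-from-pocket serine mutation
        attenuations = [1.86, 0.85, 1.81]
        wt = [-40.0, -41.2, -39.5]
        pairs = [(self._result(w + a), self._result(w))
                 for a, w in zip(attenuations, wt)]
        ddgs = [delta_delta_g(m, w) for m, w in pairs]
        assert np.mean(ddgs) == pytest.approx(np.mean(attenuations))
        assert np.std(ddgs, ddof=1) == pytest.approx(np.std(attenuations, ddof=1))

    def test_mismatched_config_error(self):
        a = self._result(-8.0)
        b = self._result(-10.0)
        b.eps_in = 4.0
        with pytest.raises(ValueError, match="config"):
            delta_delta_g(a, b)
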