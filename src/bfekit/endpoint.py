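"""End-point (MM/PB(GB)SA) binding free energies under the single-trajectory
protocol.

Every frame of the complex trajectory is evaluated three times -- complex,
receptor alone, ligand alone -- on the *same* coordinates, and the binding
terms are the differences.  Because the parts keep their internal bonded
terms unchanged, dE_bond/dE_angle/dE_dihedral cancel exactly, leaving

    dH = dE_ele + dE_vdW + dG_polar + dG_SA
    dG_bind = dH - T dS                         (entropy optional)

Per-residue decomposition splits every cross pair energy half/half between
the two residues it connects; the residue sums reconstruct the totals
exactly.  The polar part of the decomposition always uses the pairwise GB
matrix (finite-difference PB is not pairwise decomposable); PB totals are
reported alongside when the PB model is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MolecularSystem, Trajectory
from .mm import bonded_energy, pair_energy_matrix
from .nma import nma_entropy
from .pb import pb_energy
from .solvation import (SolvationConfig, effective_born_radii, gb_energy_matrix,
                        lcpo_sasa, nonpolar_energy)

__all__ = ["EndpointResult", "endpoint_bfe", "per_residue_decomposition",
           "truncate_for_entropy", "binding_entropy", "delta_delta_g"]


@dataclass
class EndpointResult:
    """Per-frame and averaged binding free energy terms (kcal/mol)."""

    model: str
    eps_in: float
    n_frames: int
    per_frame: pd.DataFrame          # columns: e_ele, e_vdw, e_bonded, g_polar, g_sa, dh
    minus_t_ds: float | None = None  # -T dS_bind, kcal/mol

    @property
    def mean(self) -> pd.Series:
        return self.per_frame.mean()

    @property
    def sd(self) -> pd.Series:
        return self.per_frame.std(ddof=1)

    @property
    def dh(self) -> float:
        return float(self.per_frame["dh"].mean())

    @property
    def dg_bind(self) -> float:
        if self.minus_t_ds is None:
            return self.dh
        return self.dh + self.minus_t_ds

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"mean": self.mean, "sd": self.sd})
        return out


def _species_systems(system: MolecularSystem):
    if not system.ligand_mask or not system.receptor_mask:
        raise ValueError("ligand and receptor masks must both be non-empty")
    rec = system.subset(system.receptor_mask)
    lig = system.subset(system.ligand_mask)
    return rec, lig


def _cross_mask_bonded(system: MolecularSystem, frame: np.ndarray) -> float:
    """Bonded energy of terms spanning the ligand/receptor partition.

    This is the exact complex-minus-parts bonded difference: terms wholly
    inside one mask appear identically in the complex and in that part.
    """
    lig = system.ligand_mask
    spans = lambda *ix: any(i in lig for i in ix) and not all(i in lig for i in ix)
    cross = MolecularSystem(
        system.atoms,
        [b for b in system.bonds if spans(b.i, b.j)],
        [a for a in system.angles if spans(a.i, a.j, a.k_atom)],
        [d for d in system.dihedrals if spans(d.i, d.j, d.k_atom, d.l)],
        exclusions={})
    return float(sum(bonded_energy(cross, frame)))


def _polar_total(system, frame, config):
    if config.model.upper() == "PB":
        return pb_energy(system, frame, config)
    return float(gb_energy_matrix(system, frame, config).sum())


def endpoint_bfe(system: MolecularSystem, trajectory: Trajectory,
                 config: SolvationConfig | None = None) -> EndpointResult:
    """Trajectory-averaged MM/PB(GB)SA binding terms (no entropy)."""
    config = config or SolvationConfig()
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    rec_sys, lig_sys = _species_systems(system)
    rec_idx = sorted(system.receptor_mask)
    lig_idx = sorted(system.ligand_mask)
    rows = []
    for fi, frame in enumerate(trajectory):
        rec_fr = frame[rec_idx]
        lig_fr = frame[lig_idx]
        # gas phase: nonbonded cross terms + bonded cancellation check
        ele_m, vdw_m = pair_energy_matrix(system, frame, config.eps_in)
        a = np.zeros(system.n_atoms, bool); a[lig_idx] = True
        b = np.zeros(system.n_atoms, bool); b[rec_idx] = True
        cross = np.outer(a, b)
        d_ele = float(ele_m[cross].sum())
        d_vdw = float(vdw_m[cross].sum())
        # complex-minus-parts bonded difference equals the sum of terms that
        # span both masks; with a clean partition it is exactly zero (the
        # single-trajectory cancellation), with no floating-point residue
        d_bonded = _cross_mask_bonded(system, frame)
        # solvation
        g_pol = (_polar_total(system, frame, config)
                 - _polar_total(rec_sys, rec_fr, config)
                 - _polar_total(lig_sys, lig_fr, config))
        g_sa = (nonpolar_energy(lcpo_sasa(system, frame, config.probe_radius), config)
                - nonpolar_energy(lcpo_sasa(rec_sys, rec_fr, config.probe_radius), config)
                - nonpolar_energy(lcpo_sasa(lig_sys, lig_fr, config.probe_radius), config))
        dh = d_ele + d_vdw + d_bonded + g_pol + g_sa
        if not np.isfinite(dh):
            raise ValueError(f"non-finite energy on frame {fi}")
        rows.append(dict(e_ele=d_ele, e_vdw=d_vdw, e_bonded=d_bonded,
                         g_polar=g_pol, g_sa=g_sa, dh=dh))
    df = pd.DataFrame(rows)
    return EndpointResult(model=config.model.upper(), eps_in=config.eps_in,
                          n_frames=len(df), per_frame=df)


# ---------------------------------------------------------------------------
# per-residue decomposition
# ---------------------------------------------------------------------------

def per_residue_decomposition(system: MolecularSystem, trajectory: Trajectory,
                              config: SolvationConfig | None = None) -> pd.DataFrame:
    """Per-residue ele/vdW/polar/nonpolar/total binding contributions.

    The ligand appears as one row (residue of its first atom).  Columns sum
    to the GB-model binding totals; with ``model='PB'`` the polar column is
    still the pairwise GB decomposition (documented approximation).
    """
    config = config or SolvationConfig()
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    gb_cfg = SolvationConfig(model="GB", eps_in=config.eps_in, eps_out=config.eps_out,
                             gamma=config.gamma, b=config.b,
                             probe_radius=config.probe_radius)
    rec_sys, lig_sys = _species_systems(system)
    rec_idx = sorted(system.receptor_mask)
    lig_idx = sorted(system.ligand_mask)
    n = system.n_atoms
    atom_res = np.array([a.residue_id for a in system.atoms])
    res_ids = system.residue_ids()
    acc = {rid: np.zeros(4) for rid in res_ids}   # ele, vdw, polar, nonpolar
    a = np.zeros(n, bool); a[lig_idx] = True
    bmask = np.zeros(n, bool); bmask[rec_idx] = True
    cross = np.outer(a, bmask) | np.outer(bmask, a)

    for frame in trajectory:
        rec_fr = frame[rec_idx]
        lig_fr = frame[lig_idx]
        ele_m, vdw_m = pair_energy_matrix(system, frame, config.eps_in)
        # gas terms: cross pairs only, half to each residue
        half_ele = np.where(cross, ele_m, 0.0) * 0.5
        half_vdw = np.where(cross, vdw_m, 0.0) * 0.5
        # polar: complex pairwise matrix minus parts matrices (embedded)
        gbm_c = gb_energy_matrix(system, frame, gb_cfg)
        d_gb = gbm_c.copy()
        gbm_r = gb_energy_matrix(rec_sys, rec_fr, gb_cfg)
        gbm_l = gb_energy_matrix(lig_sys, lig_fr, gb_cfg)
        d_gb[np.ix_(rec_idx, rec_idx)] -= gbm_r
        d_gb[np.ix_(lig_idx, lig_idx)] -= gbm_l
        # each triangle entry already holds half the pair energy (the Still
        # double sum), so a row sum is exactly the half/half split; the
        # diagonal (self) term belongs to its atom outright
        pol_atom = d_gb.sum(axis=1)
        # nonpolar: per-atom delta SASA
        sasa_c = lcpo_sasa(system, frame, config.probe_radius).per_atom
        d_sasa = sasa_c.copy()
        d_sasa[rec_idx] -= lcpo_sasa(rec_sys, rec_fr, config.probe_radius).per_atom
        d_sasa[lig_idx] -= lcpo_sasa(lig_sys, lig_fr, config.probe_radius).per_atom
        np_atom = config.gamma * d_sasa
        # half/half split: the row sum over a residue's atoms collects half of
        # every cross pair incident to it (the other half sits in the partner
        # residue's rows), so residue sums reconstruct the totals exactly.
        for rid in res_ids:
            sel = atom_res == rid
            acc[rid][0] += half_ele[sel, :].sum()
            acc[rid][1] += half_vdw[sel, :].sum()
            acc[rid][2] += pol_atom[sel].sum()
            acc[rid][3] += np_atom[sel].sum()

    nf = len(trajectory)
    rows = []
    res_names = {a_.residue_id: a_.residue_name for a_ in system.atoms}
    for rid in res_ids:
        ele, vdw, pol, npol = acc[rid] / nf
        rows.append(dict(residue_id=rid, residue_name=res_names[rid],
                         ele=ele, vdw=vdw, polar=pol, nonpolar=npol,
                         total=ele + vdw + pol + npol))
    return pd.DataFrame(rows).set_index("residue_id")


def truncate_for_entropy(system: MolecularSystem, frame: np.ndarray,
                         cutoff: float = 9.0):
    """Residues with any heavy atom within ``cutoff`` of any ligand heavy
    atom, included whole, plus the ligand.  Returns ``(subset_system,
    subset_frame, info)``; ``info`` records kept residues and chain breaks
    (termini of discontinuous fragments, treated as charged groups in the
    reference protocol -- recorded, not rebuilt)."""
    frame = np.asarray(frame, float)
    if not system.ligand_mask:
        raise ValueError("ligand mask must be set")
    heavy = system.heavy
    lig = [i for i in sorted(system.ligand_mask) if heavy[i]]
    if not lig:
        raise ValueError("ligand has no heavy atoms")
    lig_xyz = frame[lig]
    keep_res = set()
    for atom in system.atoms:
        if not atom.is_heavy or atom.index in system.ligand_mask:
            continue
        d = np.linalg.norm(lig_xyz - frame[atom.index], axis=1).min()
        if d <= cutoff:
            keep_res.add(atom.residue_id)
    keep = [a.index for a in system.atoms
            if a.residue_id in keep_res] + sorted(system.ligand_mask)
    keep = sorted(set(keep))
    if not keep:
        raise ValueError("truncation produced an empty selection")
    sub = system.subset(keep)
    kept_sorted = sorted(keep_res)
    breaks = [(a, b) for a, b in zip(kept_sorted, kept_sorted[1:]) if b - a > 1]
    info = {"kept_residues": kept_sorted, "chain_breaks": breaks,
            "terminus_treatment": "charged (COO-/NH3+), recorded as metadata"}
    return sub, frame[keep], info


def binding_entropy(system: MolecularSystem, trajectory: Trajectory,
                    T: float = 300.0, cutoff: float = 9.0, n_frames: int = 5,
                    max_steps: int = 10000, convergence: float = 1e-4):
    """-T dS_bind averaged over ``n_frames`` equally spaced frames.

    Each selected frame is truncated around the ligand, minimized, and the
    complex/receptor/ligand normal-mode entropies are differenced.
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    stride = max(len(trajectory) // n_frames, 1)
    picks = list(range(0, len(trajectory), stride))[:n_frames]
    vals = []
    for fi in picks:
        sub, sub_fr, _ = truncate_for_entropy(system, trajectory.frames[fi], cutoff)
        rec = sub.subset(sub.receptor_mask)
        lig = sub.subset(sub.ligand_mask)
        rec_fr = sub_fr[sorted(sub.receptor_mask)]
        lig_fr = sub_fr[sorted(sub.ligand_mask)]
        s_c = nma_entropy(sub, sub_fr, T, max_steps, convergence)
        s_r = nma_entropy(rec, rec_fr, T, max_steps, convergence)
        s_l = nma_entropy(lig, lig_fr, T, max_steps, convergence)
        vals.append(-T * (s_c.s_total - s_r.s_total - s_l.s_total))
    return float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")


def delta_delta_g(result_mut: EndpointResult, result_wt: EndpointResult) -> float:
    """ddG = dG_mut - dG_wt; positive means the mutation weakens binding."""
    if (result_mut.model, result_mut.eps_in) != (result_wt.model, result_wt.eps_in):
        raise ValueError("results were computed with different configurations")
    return result_mut.dg_bind - result_wt.dg_bind
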