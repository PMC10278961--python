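"""Molecular-mechanics energy terms.

AMBER functional forms: harmonic bonds ``k (r - r0)^2`` and angles
``k (theta - theta0)^2``, cosine dihedrals ``(V_n/2)(1 + cos(n phi - gamma))``,
Coulomb ``332.0637 q_i q_j / (eps_in r)`` and Lennard-Jones in the
Rmin/epsilon convention with Lorentz-Berthelot combination.  Nonbonded sums
run over all pairs (no cutoff; these are post-processing energies), honouring
the system's 1-2/1-3 exclusions and scaled 1-4 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB
from .core import MolecularSystem

__all__ = ["MMEnergyReport", "bonded_energy", "coulomb_energy", "lj_energy",
           "interaction_energy", "pair_energy_matrix", "total_mm_energy"]

_MIN_DIST = 1e-8


@dataclass
class MMEnergyReport:
    """Per-term MM energies (kcal/mol)."""

    e_bond: float
    e_angle: float
    e_dihedral: float
    e_ele: float
    e_vdw: float

    @property
    def total(self) -> float:
        return self.e_bond + self.e_angle + self.e_dihedral + self.e_ele + self.e_vdw


def bonded_energy(system: MolecularSystem, frame: np.ndarray):
    """Return ``(e_bond, e_angle, e_dihedral)`` in kcal/mol."""
    frame = np.asarray(frame, float)
    e_bond = 0.0
    for b in system.bonds:
        d = frame[b.j] - frame[b.i]
        r = np.linalg.norm(d)
        if r < _MIN_DIST:
            raise ValueError(f"zero-length bond vector between atoms {b.i} and {b.j}")
        e_bond += b.k * (r - b.r0) ** 2
    e_angle = 0.0
    for a in system.angles:
        v1 = frame[a.i] - frame[a.j]
        v2 = frame[a.k_atom] - frame[a.j]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        theta = np.arccos(np.clip(cosang, -1.0, 1.0))
        e_angle += a.k * (theta - a.theta0) ** 2
    e_dihedral = 0.0
    for d in system.dihedrals:
        phi = dihedral_angle(frame[d.i], frame[d.j], frame[d.k_atom], frame[d.l])
        e_dihedral += 0.5 * d.vn * (1.0 + np.cos(d.n * phi - d.gamma))
    return float(e_bond), float(e_angle), float(e_dihedral)


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in radians (IUPAC convention)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.arctan2(y, x))


def _pair_scales(system: MolecularSystem, n: int):
    """(ele_scale, vdw_scale) matrices encoding exclusions/1-4 scaling."""
    se = np.ones((n, n))
    sv = np.ones((n, n))
    for (i, j), (e, v) in system.exclusions.items():
        se[i, j] = se[j, i] = e
        sv[i, j] = sv[j, i] = v
    np.fill_diagonal(se, 0.0)
    np.fill_diagonal(sv, 0.0)
    return se, sv


def pair_energy_matrix(system: MolecularSystem, frame: np.ndarray, eps_in: float = 1.0):
    """Full symmetric per-pair Coulomb and LJ energy matrices (kcal/mol).

    Entry ``[i, j]`` is the complete pair energy (each pair counted in both
    triangles; sum a triangle to get totals).  Exclusion/1-4 scales applied.
    """
    frame = np.asarray(frame, float)
    n = system.n_atoms
    diff = frame[:, None, :] - frame[None, :, :]
    r = np.sqrt((diff ** 2).sum(-1))
    np.fill_diagonal(r, np.inf)
    se, sv = _pair_scales(system, n)
    if np.any((r < _MIN_DIST) & ((se > 0) | (sv > 0))):
        raise ValueError("coincident atoms in an interacting pair")
    q = system.charges
    ele = COULOMB * np.outer(q, q) / (eps_in * r) * se
    rmin = system.rmin_half[:, None] + system.rmin_half[None, :]
    epsm = np.sqrt(np.outer(system.epsilons, system.epsilons))
    with np.errstate(over="ignore"):
        x6 = (rmin / r) ** 6
    vdw = epsm * (x6 ** 2 - 2.0 * x6) * sv
    return ele, vdw


def coulomb_energy(system: MolecularSystem, frame: np.ndarray, eps_in: float = 1.0,
                   group_a=None, group_b=None) -> float:
    """Coulomb energy between two atom groups (defaults: all atoms).

    Exclusions and 1-4 scaling are honoured; intra-group pairs are counted
    once when ``group_a == group_b``.
    """
    ele, _ = pair_energy_matrix(system, frame, eps_in)
    return _sum_groups(system, ele, group_a, group_b)


def lj_energy(system: MolecularSystem, frame: np.ndarray,
              group_a=None, group_b=None) -> float:
    """Lennard-Jones energy between two atom groups (defaults: all atoms)."""
    _, vdw = pair_energy_matrix(system, frame, 1.0)
    return _sum_groups(system, vdw, group_a, group_b)


def _sum_groups(system, mat, group_a, group_b) -> float:
    n = system.n_atoms
    if group_a is None:
        group_a = range(n)
    if group_b is None:
        group_b = range(n)
    ga, gb = set(group_a), set(group_b)
    if not ga or not gb:
        raise ValueError("empty atom group")
    a = np.zeros(n, bool)
    b = np.zeros(n, bool)
    a[list(ga)] = True
    b[list(gb)] = True
    if ga == gb:
        mask = np.triu(np.outer(a, a), k=1)
    elif ga & gb:
        raise ValueError("groups must be identical or disjoint")
    else:
        mask = np.outer(a, b)
    return float(mat[mask].sum())


def interaction_energy(system: MolecularSystem, frame: np.ndarray,
                       eps_in: float = 1.0) -> tuple[float, float]:
    """Gas-phase ligand-receptor interaction ``(dE_ele, dE_vdw)``.

    Under the single-trajectory convention this equals the complex-minus-parts
    difference of the nonbonded energies evaluated on the same coordinates.
    """
    if not system.ligand_mask or not system.receptor_mask:
        raise ValueError("ligand/receptor masks must be set and non-empty")
    ele, vdw = pair_energy_matrix(system, frame, eps_in)
    e = _sum_groups(system, ele, system.ligand_mask, system.receptor_mask)
    v = _sum_groups(system, vdw, system.ligand_mask, system.receptor_mask)
    return e, v


def total_mm_energy(system: MolecularSystem, frame: np.ndarray,
                    eps_in: float = 1.0) -> MMEnergyReport:
    """All five MM terms over the whole system."""
    eb, ea, ed = bonded_energy(system, frame)
    ele, vdw = pair_energy_matrix(system, frame, eps_in)
    iu = np.triu_indices(system.n_atoms, k=1)
    return MMEnergyReport(eb, ea, ed, float(ele[iu].sum()), float(vdw[iu].sum()))
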