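"""Implicit solvation: generalized Born (OBC variant 1), LCPO surface area,
and the linear nonpolar term.

The polar contribution uses the Still pairwise form

    dG_pol = -(k/2) (1/eps_in - 1/eps_out) sum_ij q_i q_j / f_GB(r, R_i, R_j)

with ``f_GB = sqrt(r^2 + R_i R_j exp(-r^2 / (4 R_i R_j)))`` and effective
radii from the pairwise-descreening (HCT) integral rescaled through the OBC
tanh correction (alpha=0.8, beta=0, gamma=2.909125; 0.09 A intrinsic-radius
offset).  The nonpolar contribution is ``gamma * SASA + b`` with the surface
area from the linear-combination-of-pairwise-overlaps (LCPO) approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import (COULOMB, GB_OFFSET, OBC1_ALPHA, OBC1_BETA, OBC1_GAMMA,
                        PROBE_RADIUS, SASA_B, SASA_GAMMA)
from .core import MolecularSystem

__all__ = ["SolvationConfig", "SASAResult", "effective_born_radii",
           "gb_energy", "gb_energy_matrix", "lcpo_sasa", "nonpolar_energy"]


@dataclass
class SolvationConfig:
    """Settings for the polar and nonpolar solvation terms."""

    model: str = "GB"                 # "GB" or "PB"
    eps_in: float = 1.0
    eps_out: float = 80.0
    gamma: float = SASA_GAMMA         # kcal/(mol A^2)
    b: float = SASA_B                 # kcal/mol
    probe_radius: float = PROBE_RADIUS
    pb_grid_spacing: float = 0.5      # A
    pb_tolerance: float = 1e-6
    pb_max_iterations: int = 20000

    def __post_init__(self):
        if self.model.upper() not in ("GB", "PB"):
            raise ValueError("model must be 'GB' or 'PB'")
        if not (self.eps_out > self.eps_in > 0):
            raise ValueError("require eps_out > eps_in > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class SASAResult:
    total: float                 # A^2
    per_atom: np.ndarray         # A^2, zero for atoms outside the surface set


# ---------------------------------------------------------------------------
# generalized Born
# ---------------------------------------------------------------------------

def _hct_integral(r: float, rho_i: float, s_j: float) -> float:
    """Pairwise descreening integral of atom j's screened sphere (radius
    ``s_j``) against atom i (van der Waals radius ``rho_i``), both offsets
    already applied.  Units 1/A."""
    if rho_i >= r + s_j:
        return 0.0
    u = r + s_j
    if rho_i > abs(r - s_j):
        low = rho_i
    else:
        low = abs(r - s_j)
    term = (1.0 / low - 1.0 / u
            + 0.25 * (r - s_j * s_j / r) * (1.0 / (u * u) - 1.0 / (low * low))
            + 0.5 / r * np.log(low / u))
    integral = 0.5 * term
    if rho_i < s_j - r:
        # atom i fully inside the descreening sphere of j
        integral += 1.0 / rho_i - 1.0 / low
    return integral


def effective_born_radii(system: MolecularSystem, frame: np.ndarray) -> np.ndarray:
    """Per-atom effective Born radii (A) with the OBC1 tanh rescaling."""
    frame = np.asarray(frame, float)
    rho = system.gb_radii
    screen = system.gb_screens
    if np.any(rho <= 0):
        bad = np.where(rho <= 0)[0]
        raise ValueError(f"atoms {bad.tolist()} lack GB radii")
    rho_t = rho - GB_OFFSET
    n = system.n_atoms
    radii = np.empty(n)
    for i in range(n):
        integral = 0.0
        for j in range(n):
            if i == j:
                continue
            r = float(np.linalg.norm(frame[i] - frame[j]))
            integral += _hct_integral(r, rho_t[i], screen[j] * rho_t[j])
        psi = integral * rho_t[i]
        inv = (1.0 / rho_t[i]
               - np.tanh(OBC1_ALPHA * psi - OBC1_BETA * psi ** 2
                         + OBC1_GAMMA * psi ** 3) / rho[i])
        if inv <= 0:
            raise ValueError(f"non-positive effective Born radius for atom {i}")
        radii[i] = 1.0 / inv
    return radii


def gb_energy_matrix(system: MolecularSystem, frame: np.ndarray,
                     config: SolvationConfig | None = None,
                     born_radii: np.ndarray | None = None) -> np.ndarray:
    """Symmetric per-pair polar energy matrix (kcal/mol).

    Diagonal holds the Born self terms; off-diagonal entries hold half the
    pair energy in each triangle so that the full matrix sums to the total.
    """
    config = config or SolvationConfig()
    frame = np.asarray(frame, float)
    if born_radii is None:
        born_radii = effective_born_radii(system, frame)
    if np.any(born_radii <= 0):
        raise ValueError("non-positive effective Born radius")
    q = system.charges
    diff = frame[:, None, :] - frame[None, :, :]
    r2 = (diff ** 2).sum(-1)
    rr = np.outer(born_radii, born_radii)
    f_gb = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
    pref = -0.5 * COULOMB * (1.0 / config.eps_in - 1.0 / config.eps_out)
    mat = pref * np.outer(q, q) / f_gb
    return mat


def gb_energy(system: MolecularSystem, frame: np.ndarray,
              config: SolvationConfig | None = None,
              born_radii: np.ndarray | None = None) -> float:
    """Total GB polar solvation free energy (kcal/mol)."""
    return float(gb_energy_matrix(system, frame, config, born_radii).sum())


# ---------------------------------------------------------------------------
# LCPO surface area
# ---------------------------------------------------------------------------

#: (P1, P2, P3, P4) keyed by (element, bonded-heavy-neighbor count).
#: Zero-neighbor entries are the exact isolated sphere.  The carbon sp3 and
#: oxygen rows follow the published LCPO parameterization; other elements
#: fall back to the sp3-carbon row of matching neighbor count.
_LCPO_PARAMS = {
    ("C", 0): (1.0, 0.0, 0.0, 0.0),
    ("C", 1): (0.77887, -0.28063, -0.0012968, 0.00039328),
    ("C", 2): (0.56482, -0.19608, -0.0010219, 0.0002658),
    ("C", 3): (0.23348, -0.072627, -0.00020079, 0.00007967),
    ("C", 4): (0.0, 0.0, 0.0, 0.0),
    ("O", 0): (1.0, 0.0, 0.0, 0.0),
    ("O", 1): (0.77914, -0.25262, -0.0016056, 0.00035071),
    ("O", 2): (0.49392, -0.16038, -0.00015512, 0.00016453),
}


def _lcpo_parameters(element: str, n_bonded: int):
    key = (element.upper(), min(n_bonded, 4))
    if key in _LCPO_PARAMS:
        return _LCPO_PARAMS[key]
    fallback = ("C", min(n_bonded, 4))
    warnings.warn(f"no LCPO parameters for {key}; using generic sp3 entry "
                  f"{fallback}", stacklevel=2)
    return _LCPO_PARAMS[fallback]


def _overlap_area(R1: float, R2: float, d: float) -> float:
    """Area of sphere 1 buried inside sphere 2 (A^2); 0 when disjoint."""
    if d >= R1 + R2 or d <= 1e-12:
        return 0.0
    if d + R1 <= R2:
        return 4.0 * np.pi * R1 * R1      # sphere 1 engulfed
    if d + R2 <= R1:
        return 0.0                        # sphere 2 inside 1: surface 1 untouched
    return 2.0 * np.pi * R1 * (R1 - d / 2.0 - (R1 * R1 - R2 * R2) / (2.0 * d))


def lcpo_sasa(system: MolecularSystem, frame: np.ndarray,
              probe: float = PROBE_RADIUS,
              radii: np.ndarray | None = None) -> SASAResult:
    """Solvent-accessible surface area by linear combination of pairwise
    overlaps.  Hydrogens carry zero area.  Atom radii default to the
    Lennard-Jones Rmin/2 values."""
    frame = np.asarray(frame, float)
    if radii is None:
        radii = system.rmin_half
    radii = np.asarray(radii, float)
    heavy = system.heavy
    if np.any((radii <= 0) & heavy):
        bad = np.where((radii <= 0) & heavy)[0]
        raise ValueError(f"atoms {bad.tolist()} lack SASA radii")
    n = system.n_atoms
    R = radii + probe
    n_bonded = np.zeros(n, int)
    for b in system.bonds:
        if heavy[b.i] and heavy[b.j]:
            n_bonded[b.i] += 1
            n_bonded[b.j] += 1

    # neighbor lists: overlapping heavy spheres
    nbrs = [[] for _ in range(n)]
    for i in range(n):
        if not heavy[i]:
            continue
        for j in range(n):
            if j == i or not heavy[j]:
                continue
            d = float(np.linalg.norm(frame[i] - frame[j]))
            if d < R[i] + R[j]:
                nbrs[i].append((j, d))

    def A(i, j, d):
        return _overlap_area(R[i], R[j], d)

    per_atom = np.zeros(n)
    for i in range(n):
        if not heavy[i]:
            continue
        p1, p2, p3, p4 = _lcpo_parameters(system.atoms[i].element, n_bonded[i])
        s1 = 4.0 * np.pi * R[i] * R[i]
        sum_aij = 0.0
        sum_ajk = 0.0
        sum_aij_ajk = 0.0
        nbr_i = {j for j, _ in nbrs[i]}
        for j, dij in nbrs[i]:
            aij = A(i, j, dij)
            sum_aij += aij
            ajk_sum = 0.0
            for k, djk in nbrs[j]:
                if k == i or k not in nbr_i:
                    continue
                ajk_sum += A(j, k, djk)
            sum_ajk += ajk_sum
            sum_aij_ajk += aij * ajk_sum
        area = p1 * s1 + p2 * sum_aij + p3 * sum_ajk + p4 * sum_aij_ajk
        per_atom[i] = max(area, 0.0)
    return SASAResult(total=float(per_atom.sum()), per_atom=per_atom)


def nonpolar_energy(sasa: float | SASAResult,
                    config: SolvationConfig | None = None) -> float:
    """Nonpolar solvation free energy ``gamma * SASA + b`` (kcal/mol)."""
    config = config or SolvationConfig()
    total = sasa.total if isinstance(sasa, SASAResult) else float(sasa)
    if total < 0:
        raise ValueError("SASA must be non-negative")
    return config.gamma * total + config.b
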