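"""Normal-mode vibrational entropy on the toy force field.

The structure is first minimized (steepest descent, then conjugate
gradient) to an RMS gradient below the requested convergence, the
mass-weighted Hessian is built by central finite differences, the external
(translation + rotation) modes are removed, and the harmonic-oscillator
entropy is summed over the remaining frequencies.  Rigid-rotor rotational
and ideal-gas translational entropies complete S_total so that binding
entropies -T dS = -T (S_complex - S_receptor - S_ligand) can be formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .constants import EIG_TO_OMEGA2, KB_SI, PLANCK_SI, R_GAS
from .core import MolecularSystem
from .mm import bonded_energy, pair_energy_matrix

__all__ = ["EntropyReport", "mm_potential", "minimize_structure",
           "mass_weighted_hessian", "normal_mode_frequencies", "nma_entropy",
           "vibrational_entropy", "MinimizationError"]

_PRESSURE_PA = 101325.0
_AMU_KG = 1.66053906660e-27
_A_M = 1e-10


class MinimizationError(RuntimeError):
    def __init__(self, rms_gradient, convergence):
        self.rms_gradient = rms_gradient
        super().__init__(f"minimizer stalled at RMS gradient "
                         f"{rms_gradient:.3e} > {convergence:g} kcal/(mol A)")


def mm_potential(system: MolecularSystem, eps_in: float = 1.0):
    """Return ``energy(x_flat)`` and its central-difference gradient."""

    def energy(x):
        frame = x.reshape(-1, 3)
        eb, ea, ed = bonded_energy(system, frame)
        ele, vdw = pair_energy_matrix(system, frame, eps_in)
        iu = np.triu_indices(system.n_atoms, k=1)
        return eb + ea + ed + float(ele[iu].sum() + vdw[iu].sum())

    def gradient(x, delta=1e-5):
        g = np.empty_like(x)
        for k in range(x.size):
            xp = x.copy(); xp[k] += delta
            xm = x.copy(); xm[k] -= delta
            g[k] = (energy(xp) - energy(xm)) / (2.0 * delta)
        return g

    return energy, gradient


def minimize_structure(system: MolecularSystem, frame: np.ndarray,
                       max_steps: int = 10000, convergence: float = 1e-4,
                       eps_in: float = 1.0):
    """Minimize to RMS gradient <= ``convergence`` kcal/(mol A).

    A short steepest-descent phase relaxes close contacts before the
    conjugate-gradient stage.  Returns ``(minimized_frame, rms_gradient)``.
    """
    energy, gradient = mm_potential(system, eps_in)
    x = np.asarray(frame, float).ravel().copy()

    def rms(g):
        return float(np.sqrt(np.mean(g ** 2)))

    # steepest descent with backtracking (robust far from minimum)
    step = 1e-3
    for _ in range(min(200, max_steps)):
        g = gradient(x)
        if rms(g) <= convergence:
            return x.reshape(-1, 3), rms(g)
        e0 = energy(x)
        while step > 1e-10 and energy(x - step * g) >= e0:
            step *= 0.5
        x = x - step * g
        step = min(step * 1.2, 1.0)

    res = _scipy_minimize(energy, x, jac=gradient, method="CG",
                          options={"maxiter": max_steps, "gtol": convergence / 10})
    x = res.x
    g = gradient(x)
    if rms(g) > convergence:
        # final polish
        res = _scipy_minimize(energy, x, jac=gradient, method="BFGS",
                              options={"maxiter": max_steps, "gtol": convergence / 10})
        x = res.x
        g = gradient(x)
    if rms(g) > convergence:
        raise MinimizationError(rms(g), convergence)
    return x.reshape(-1, 3), rms(g)


def mass_weighted_hessian(system: MolecularSystem, frame: np.ndarray,
                          eps_in: float = 1.0, delta: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian, mass-weighted (kcal/mol/A^2/amu)."""
    _, gradient = mm_potential(system, eps_in)
    x = np.asarray(frame, float).ravel()
    n = x.size
    H = np.empty((n, n))
    for k in range(n):
        xp = x.copy(); xp[k] += delta
        xm = x.copy(); xm[k] -= delta
        H[:, k] = (gradient(xp) - gradient(xm)) / (2.0 * delta)
    H = 0.5 * (H + H.T)
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(system.masses), 3)
    return H * np.outer(inv_sqrt_m, inv_sqrt_m)


def _is_linear(system, frame, tol=1e-6):
    frame = np.asarray(frame, float)
    m = system.masses
    com = np.average(frame, axis=0, weights=m)
    x = frame - com
    inertia = np.einsum("a,ai,aj->ij", m, x, x)
    I = np.trace(inertia) * np.eye(3) - inertia
    ev = np.sort(np.linalg.eigvalsh(I))
    return ev[0] < tol * max(ev[-1], 1.0)


def normal_mode_frequencies(system: MolecularSystem, frame: np.ndarray,
                            eps_in: float = 1.0,
                            check_minimum: bool = True) -> np.ndarray:
    """Vibrational frequencies (Hz) after removing external modes.

    External modes: 6 (5 for linear systems, 3 for a single atom) removed by
    smallest absolute mass-weighted eigenvalue.  Raises if genuine negative
    curvature remains beyond them.
    """
    n = system.n_atoms
    if n == 1:
        return np.array([])
    Hmw = mass_weighted_hessian(system, frame, eps_in)
    evals = np.linalg.eigvalsh(Hmw)
    n_ext = 5 if _is_linear(system, frame) else 6
    n_ext = min(n_ext, 3 * n)
    order = np.argsort(np.abs(evals))
    vib = np.sort(evals[order[n_ext:]])
    if check_minimum and vib.size and vib[0] < -1e-6 * max(abs(vib[-1]), 1.0):
        raise ValueError(f"negative eigenvalue beyond the external modes "
                         f"({vib[0]:.3e}); structure is not a minimum")
    omega2 = np.clip(vib, 0.0, None) * EIG_TO_OMEGA2
    return np.sqrt(omega2) / (2.0 * np.pi)


def vibrational_entropy(frequencies_hz: np.ndarray, T: float = 300.0) -> float:
    """Harmonic-oscillator entropy, kcal/(mol K)."""
    nu = np.asarray(frequencies_hz, float)
    nu = nu[nu > 1e6]  # drop numerically-zero modes (< ~3e-5 cm^-1)
    x = PLANCK_SI * nu / (KB_SI * T)
    return float(R_GAS * np.sum(x / np.expm1(x) - np.log1p(-np.exp(-x))))


def _translational_entropy(total_mass_amu, T):
    m = total_mass_amu * _AMU_KG
    lam = (2.0 * np.pi * m * KB_SI * T) / PLANCK_SI ** 2
    q = lam ** 1.5 * (KB_SI * T / _PRESSURE_PA)
    return R_GAS * (np.log(q) + 2.5)


def _rotational_entropy(system, frame, T, sigma=1):
    n = system.n_atoms
    if n == 1:
        return 0.0
    m = system.masses
    com = np.average(frame, axis=0, weights=m)
    x = (frame - com) * _A_M
    mkg = m * _AMU_KG
    inertia = np.einsum("a,ai,aj->ij", mkg, x, x)
    I = np.trace(inertia) * np.eye(3) - inertia
    ev = np.sort(np.linalg.eigvalsh(I))
    if _is_linear(system, frame):
        Imom = ev[-1]
        q = 8.0 * np.pi ** 2 * Imom * KB_SI * T / (sigma * PLANCK_SI ** 2)
        return R_GAS * (np.log(q) + 1.0)
    q = (np.sqrt(np.pi) / sigma
         * (8.0 * np.pi ** 2 * KB_SI * T / PLANCK_SI ** 2) ** 1.5
         * np.sqrt(ev[0] * ev[1] * ev[2]))
    return R_GAS * (np.log(q) + 1.5)


@dataclass
class EntropyReport:
    """Entropy components (kcal/(mol K)) and -T S (kcal/mol) for one species."""

    s_vib: float
    s_rot: float
    s_trans: float
    T: float
    frequencies_hz: np.ndarray

    @property
    def s_total(self) -> float:
        return self.s_vib + self.s_rot + self.s_trans

    @property
    def minus_ts(self) -> float:
        return -self.T * self.s_total


def nma_entropy(system: MolecularSystem, frame: np.ndarray, T: float = 300.0,
                max_steps: int = 10000, convergence: float = 1e-4,
                eps_in: float = 1.0, minimize: bool = True) -> EntropyReport:
    """Minimize, diagonalize, and return the entropy report for one species."""
    frame = np.asarray(frame, float)
    if minimize and system.n_atoms > 1:
        frame, _ = minimize_structure(system, frame, max_steps, convergence, eps_in)
    freqs = normal_mode_frequencies(system, frame, eps_in)
    return EntropyReport(
        s_vib=vibrational_entropy(freqs, T),
        s_rot=_rotational_entropy(system, frame, T),
        s_trans=_translational_entropy(float(system.masses.sum()), T),
        T=T, frequencies_hz=freqs)
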