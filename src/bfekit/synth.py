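"""Seeded generators for every input the analysis stages consume.

Each generator is a pure function of its arguments (same seed, same output)
and returns the generated dataset together with its planted ground truth, so
every stage of the pipeline can be tested closed-loop without external data:

* :func:`make_toy_complex` -- bead-scale receptor/ligand complex with full
  force-field parameters and an optional in-pocket "mutation" that plants an
  electrostatic repulsion between the ligand and one pocket residue.
* :func:`make_correlated_trajectory` -- frames whose residues move with
  group-shared latent displacements (planted communities, guaranteed
  contacts, single-pair bridges between groups).
* :func:`make_umbrella_dataset` -- Metropolis samples from a known analytic
  PMF under the 41-window / 0.5-A / K=5 harmonic-bias layout, per round,
  with optional decaying drift in early rounds.
* :func:`make_ti_dataset` -- per-lambda Gaussian dU/dlambda samples about a
  known curve with a known integral, replicated.
* :func:`make_benchmark_pairs` -- (ddG_exp, ddG_pred) tables with a chosen
  population correlation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .core import Angle, AtomRecord, Bond, Dihedral, MolecularSystem, Trajectory
from .ti import PAPER_LAMBDA_GRID, LambdaWindow
from .wham import UmbrellaWindow, bias_potential

__all__ = ["GeneratorSpec", "generate", "make_toy_complex",
           "make_correlated_trajectory", "make_umbrella_dataset",
           "make_ti_dataset", "make_benchmark_pairs",
           "default_umbrella_layout"]


@dataclass
class GeneratorSpec:
    """Scenario id + seed + keyword parameters for :func:`generate`."""

    seed: int
    scenario: str
    params: dict = field(default_factory=dict)


_SCENARIOS = {}


def generate(spec: GeneratorSpec):
    """Dispatch a :class:`GeneratorSpec` to its generator."""
    if spec.scenario not in _SCENARIOS:
        raise ValueError(f"unknown scenario {spec.scenario!r}; "
                         f"choose from {sorted(_SCENARIOS)}")
    return _SCENARIOS[spec.scenario](seed=spec.seed, **spec.params)


def _scenario(name):
    def deco(fn):
        _SCENARIOS[name] = fn
        return fn
    return deco


# ---------------------------------------------------------------------------
# toy complexes
# ---------------------------------------------------------------------------

@_scenario("complex")
def make_toy_complex(seed: int = 0, n_receptor_residues: int = 8,
                     n_ligand_atoms: int = 5, mutate: bool = False,
                     pocket_radius: float = 6.0):
    """Bead-scale protein-pocket/ligand complex.

    Receptor residues (two heavy beads each, CA on a ring of
    ``pocket_radius`` around the pocket, CB pointing inward) surround a small
    chain ligand.  Residue ids start at 1001 for the receptor; the ligand is
    residue 1.  With ``mutate=True`` the contact residue's inward bead charge
    is sign-flipped, planting a ligand-residue electrostatic repulsion.

    Returns ``(system, frame, truth)`` where ``truth`` records the contact
    residue and the planted charges.
    """
    rng = np.random.default_rng(seed)
    atoms, coords, bonds, angles = [], [], [], []

    # --- ligand: short chain along z through the pocket center.  The anchor
    # atom sits at the chain midpoint (the receptor-bead plane, z ~ 0) and
    # carries a fixed +0.3 e; the remaining charges are mirror-antisymmetric
    # in z, so their fields cancel exactly at every in-plane receptor bead
    # and the planted contact interaction has a guaranteed sign.
    anchor = (n_ligand_atoms - 1) // 2
    lig_q = [0.0] * n_ligand_atoms
    lig_q[anchor] = 0.3
    for i in range(n_ligand_atoms // 2):
        j = n_ligand_atoms - 1 - i
        if i != anchor and j != anchor:
            lig_q[i] = float(rng.uniform(-0.15, 0.15))
            lig_q[j] = -lig_q[i]
    for i in range(n_ligand_atoms):
        q = lig_q[i]
        atoms.append(AtomRecord(len(atoms), f"L{i + 1}", "C", 1, "LIG", "L",
                                charge=q, lj_rmin_half=1.7,
                                lj_epsilon=0.09, gb_radius=1.7, gb_screen=0.72))
        coords.append([0.0, 0.0, (i - (n_ligand_atoms - 1) / 2) * 1.45])
        if i > 0:
            bonds.append(Bond(len(atoms) - 2, len(atoms) - 1,
                              float(rng.uniform(250, 400)), 1.45))
        if i > 1:
            angles.append(Angle(len(atoms) - 3, len(atoms) - 2, len(atoms) - 1,
                                float(rng.uniform(40, 70)), np.deg2rad(180.0)))
    lig_idx = list(range(len(atoms)))

    # --- receptor: ring of 2-bead residues
    contact_res = 1001   # residue whose CB pairs with ligand atom 0
    rec_idx = []
    cb_charges = {}
    for r in range(n_receptor_residues):
        rid = 1001 + r
        theta = 2.0 * np.pi * r / n_receptor_residues
        ca = np.array([pocket_radius * np.cos(theta),
                       pocket_radius * np.sin(theta), 0.0])
        cb = ca * (pocket_radius - 1.5) / pocket_radius
        ca_i = len(atoms)
        atoms.append(AtomRecord(ca_i, "CA", "C", rid, "GLY", "A",
                                charge=float(rng.uniform(-0.1, 0.1)),
                                lj_rmin_half=1.9, lj_epsilon=0.11,
                                gb_radius=1.7, gb_screen=0.72))
        coords.append(ca)
        cb_i = len(atoms)
        if rid == contact_res:
            qcb = 0.3 if mutate else -0.3
        else:
            qcb = float(rng.uniform(-0.2, 0.2))
        cb_charges[rid] = qcb
        atoms.append(AtomRecord(cb_i, "CB", "O", rid, "GLY", "A",
                                charge=qcb, lj_rmin_half=1.66, lj_epsilon=0.21,
                                gb_radius=1.5, gb_screen=0.85))
        coords.append(cb)
        bonds.append(Bond(ca_i, cb_i, float(rng.uniform(300, 500)), 1.5))
        rec_idx += [ca_i, cb_i]
        if r > 0:
            prev_ca = ca_i - 2
            d = float(np.linalg.norm(np.array(coords[ca_i]) - np.array(coords[prev_ca])))
            bonds.append(Bond(prev_ca, ca_i, float(rng.uniform(150, 300)), d))
            angles.append(Angle(cb_i, ca_i, prev_ca, float(rng.uniform(30, 60)),
                                _angle(coords[cb_i], coords[ca_i], coords[prev_ca])))
    # neutralize overall receptor drift in charge
    system = MolecularSystem(atoms, bonds, angles, [], None, lig_idx, rec_idx)
    frame = np.asarray(coords, float)
    truth = {"contact_residue": contact_res, "contact_cb_charge": cb_charges[contact_res],
             "ligand_anchor_charge": lig_q[anchor], "mutated": bool(mutate)}
    return system, frame, truth


def _angle(a, b, c):
    v1 = np.asarray(a, float) - np.asarray(b, float)
    v2 = np.asarray(c, float) - np.asarray(b, float)
    return float(np.arccos(np.clip(np.dot(v1, v2)
                                   / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)))


# ---------------------------------------------------------------------------
# correlated-motion trajectories
# ---------------------------------------------------------------------------

@_scenario("correlated_trajectory")
def make_correlated_trajectory(seed: int = 0, group_sizes=(9, 9),
                               n_frames: int = 200, sigma_latent: float = 0.15,
                               sigma_noise: float = 0.015,
                               grid_spacing: float = 3.8,
                               bridge_distance: float = 4.0):
    """One-bead-per-residue trajectory with planted motion communities.

    Each group is a compact 3xM grid (spacing below the contact cutoff);
    consecutive groups touch through exactly one residue pair placed
    ``bridge_distance`` apart.  All residues of a group share one latent
    Gaussian displacement per frame (scale ``sigma_latent``) plus independent
    noise (``sigma_noise``).

    Returns ``(system, trajectory, labels)`` with ``labels[i]`` the planted
    community of residue i.
    """
    rng = np.random.default_rng(seed)
    coords, labels, atoms = [], [], []
    x_off = 0.0
    # consecutive groups touch through their row-0 corner residues, one pair
    # at bridge_distance; every other inter-group pair is >= one grid cell
    # farther away
    for g, size in enumerate(group_sizes):
        ncols = int(np.ceil(size / 3))
        y_base = (g % 2) * 2 * grid_spacing  # stagger so only one row aligns
        for k in range(size):
            row, col = k % 3, k // 3
            coords.append([x_off + col * grid_spacing,
                           y_base + row * grid_spacing, 0.0])
            labels.append(g)
        x_off += (ncols - 1) * grid_spacing + bridge_distance

    coords = np.asarray(coords, float)
    labels = np.asarray(labels, int)
    for i in range(len(coords)):
        atoms.append(AtomRecord(i, "CA", "C", i + 1, "GLY", "A",
                                charge=0.0, lj_rmin_half=1.9, lj_epsilon=0.1,
                                gb_radius=1.7, gb_screen=0.72))
    system = MolecularSystem(atoms)

    frames = np.empty((n_frames, len(coords), 3))
    for f in range(n_frames):
        frame = coords.copy()
        for g in range(len(group_sizes)):
            latent = rng.normal(0.0, sigma_latent, size=3)
            frame[labels == g] += latent
        frame += rng.normal(0.0, sigma_noise, size=frame.shape)
        frames[f] = frame
    return system, Trajectory(frames), labels


# ---------------------------------------------------------------------------
# umbrella sampling
# ---------------------------------------------------------------------------

def default_umbrella_layout():
    """41 windows, xi_ref = 12.5 ... 32.5 A every 0.5 A, K = 5 kcal/(mol A^2)."""
    return [(12.5 + 0.5 * i, 5.0) for i in range(41)]


def _metropolis_1d(u_total, x0, n_samples, rng, burn_fraction=0.1,
                   target_acceptance=(0.3, 0.5), step0=0.5):
    """Vectorized-in-windows Metropolis chains with step auto-tuning."""
    x = np.array(x0, float)
    step = np.full_like(x, step0)
    n_burn = max(int(n_samples * burn_fraction), 50)
    out = np.empty((n_samples, len(x)))
    acc = np.zeros(len(x))
    tries = 0
    for it in range(n_burn + n_samples):
        prop = x + rng.uniform(-1, 1, size=x.shape) * step
        du = u_total(prop) - u_total(x)
        accept = rng.random(size=x.shape) < np.exp(np.clip(-du, -700, 0))
        x = np.where(accept, prop, x)
        acc += accept
        tries += 1
        if it < n_burn and tries % 25 == 0:
            rate = acc / tries if np.isscalar(tries) else acc / tries
            step = np.where(rate < target_acceptance[0], step * 0.8, step)
            step = np.where(rate > target_acceptance[1], step * 1.25, step)
            acc[:] = 0
            tries = 0
        if it >= n_burn:
            out[it - n_burn] = x
    return out


@_scenario("umbrella")
def make_umbrella_dataset(seed: int = 0, true_pmf=None, layout=None,
                          n_samples: int = 1000, T: float = 300.0,
                          n_rounds: int = 1, drift_amplitude: float = 0.0,
                          drift_tau: float = 4.0, zero_temperature: bool = False):
    """Biased Metropolis samples from a known PMF, one window list per round.

    ``true_pmf`` defaults to the harmonic well ``0.5 (xi - 20)^2``.  With
    ``drift_amplitude > 0`` round r samples from the PMF plus a bump decaying
    as ``exp(-r / drift_tau)``, emulating slow convergence; the last rounds
    approach the true profile.  ``zero_temperature`` collapses samples onto
    the minima of bias + PMF (a degenerate-limit check).

    Returns ``(rounds, truth)`` where ``rounds`` is a list (one per round) of
    :class:`~bfekit.wham.UmbrellaWindow` lists and ``truth`` holds the PMF
    callable and layout.
    """
    if true_pmf is None:
        true_pmf = lambda xi: 0.5 * (xi - 20.0) ** 2
    if layout is None:
        layout = default_umbrella_layout()
    rng = np.random.default_rng(seed)
    rounds = []
    for r in range(n_rounds):
        if drift_amplitude:
            amp = drift_amplitude * np.exp(-r / drift_tau)
            pmf_r = lambda xi, a=amp: true_pmf(xi) + a * np.exp(-0.5 * ((xi - 17.0) / 1.5) ** 2)
        else:
            pmf_r = true_pmf
        refs = np.array([x for x, _ in layout])
        ks = np.array([k for _, k in layout])

        def u_total(x, pmf=pmf_r, refs=refs, ks=ks):
            return (np.asarray(pmf(x), float)
                    + 0.5 * ks * (np.asarray(x) - refs) ** 2) / (KB * T)

        if zero_temperature:
            from scipy.optimize import minimize_scalar
            windows = []
            for (ref, k) in layout:
                res = minimize_scalar(lambda x: pmf_r(x) + 0.5 * k * (x - ref) ** 2,
                                      bounds=(ref - 2, ref + 2), method="bounded")
                windows.append(UmbrellaWindow(ref, k,
                                              np.full(n_samples, res.x)))
            rounds.append(windows)
            continue
        samples = _metropolis_1d(u_total, refs, n_samples, rng)
        rounds.append([UmbrellaWindow(ref, k, samples[:, i])
                       for i, (ref, k) in enumerate(layout)])
    truth = {"true_pmf": true_pmf, "layout": list(layout), "T": T,
             "n_samples": n_samples, "drift_amplitude": drift_amplitude}
    return rounds, truth


# ---------------------------------------------------------------------------
# thermodynamic integration
# ---------------------------------------------------------------------------

@_scenario("ti")
def make_ti_dataset(seed: int = 0, dudl=None, noise: float = 1.0,
                    n_samples: int = 1000, n_replicas: int = 5,
                    lambdas=PAPER_LAMBDA_GRID):
    """Gaussian dU/dlambda samples about a known curve, per replica.

    ``dudl`` defaults to a smooth cubic; the exact integral of the default is
    part of the returned truth (computed by dense quadrature for arbitrary
    callables).  Returns ``(replicas, truth)`` with ``replicas`` a list of
    :class:`~bfekit.ti.LambdaWindow` lists.
    """
    if dudl is None:
        dudl = lambda lam: 3.0 * lam ** 2 + 2.0 * lam - 1.0
    rng = np.random.default_rng(seed)
    lams = np.asarray(sorted(lambdas), float)
    replicas = []
    for _ in range(n_replicas):
        wins = [LambdaWindow(lam, rng.normal(dudl(lam), noise, size=n_samples))
                for lam in lams]
        replicas.append(wins)
    grid = np.linspace(0.0, 1.0, 20001)
    true_dg = float(np.trapezoid(np.asarray(dudl(grid), float), grid))
    truth = {"true_dg": true_dg, "noise": noise, "n_samples": n_samples,
             "lambdas": lams.tolist()}
    return replicas, truth


# ---------------------------------------------------------------------------
# benchmark pairs
# ---------------------------------------------------------------------------

@_scenario("benchmark")
def make_benchmark_pairs(seed: int = 0, n: int = 28, rho: float = 0.6,
                         exp_mean: float = 1.5, exp_sd: float = 1.5,
                         pred_sd: float = 1.5):
    """Bivariate-normal (ddG_exp, ddG_pred) pairs with correlation ``rho``.

    Returns ``(exp, pred, truth)``.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    exp = exp_mean + exp_sd * z1
    pred = exp_mean + pred_sd * (rho * z1 + np.sqrt(1.0 - rho ** 2) * z2)
    return exp, pred, {"rho": rho, "n": n}


def write_truth_sidecar(path, truth: dict):
    """Ground-truth sidecar (JSON; callables stored by repr)."""
    clean = {k: (repr(v) if callable(v) else v) for k, v in truth.items()}
    with open(path, "w") as fh:
        json.dump(clean, fh, indent=1, default=str)
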