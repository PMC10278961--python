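"""Finite-difference linearized Poisson-Boltzmann reaction-field energies.

Zero ionic strength, cubic grid, 7-point stencil with harmonic-mean face
dielectrics and a one-cell harmonically smoothed dielectric boundary.  The
potential of the uniform-dielectric reference state is solved on the same
grid with the same trilinear charge spreading so the grid self-energy
cancels in

    dG_pol = 1/2 sum_i q_i (phi_solvated - phi_reference)(r_i).

Boundary conditions are Debye-Hueckel (Coulomb/eps_out) on a coarse grid,
focused onto the final fine grid.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import cg

from .constants import COULOMB
from .core import MolecularSystem
from .solvation import SolvationConfig

__all__ = ["pb_energy", "PBConvergenceError"]

_FOUR_PI_K = 4.0 * np.pi * COULOMB


class PBConvergenceError(RuntimeError):
    """Iterative solve failed; carries the final residual."""

    def __init__(self, residual, max_iterations):
        self.residual = residual
        super().__init__(f"PB solver did not converge within {max_iterations} "
                         f"iterations (residual {residual:.3e})")


def _grid_axes(lo, hi, h):
    n = [int(np.ceil((hi[d] - lo[d]) / h)) + 1 for d in range(3)]
    axes = [lo[d] + h * np.arange(n[d]) for d in range(3)]
    return axes


def _node_dielectric(axes, coords, radii, eps_in, eps_out, h):
    """Per-node dielectric with a one-cell harmonic (inverse-eps) boundary mix."""
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    frac = np.zeros(X.shape)
    for c, r in zip(coords, radii):
        d = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
        f = np.clip((r + 0.5 * h - d) / h, 0.0, 1.0)
        np.maximum(frac, f, out=frac)
    inv_eps = frac / eps_in + (1.0 - frac) / eps_out
    return 1.0 / inv_eps


def _spread_charges(axes, coords, charges):
    """Trilinear charge spreading onto grid nodes."""
    shape = tuple(len(a) for a in axes)
    qn = np.zeros(shape)
    h = axes[0][1] - axes[0][0]
    lo = np.array([a[0] for a in axes])
    for c, q in zip(coords, charges):
        g = (c - lo) / h
        i0 = np.clip(np.floor(g).astype(int), 0, np.array(shape) - 2)
        t = g - i0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = ((t[0] if dx else 1 - t[0])
                         * (t[1] if dy else 1 - t[1])
                         * (t[2] if dz else 1 - t[2]))
                    qn[i0[0] + dx, i0[1] + dy, i0[2] + dz] += q * w
    return qn


def _interp(axes, phi, points):
    """Trilinear interpolation of a grid field at arbitrary points."""
    h = axes[0][1] - axes[0][0]
    lo = np.array([a[0] for a in axes])
    shape = phi.shape
    out = np.empty(len(points))
    for m, p in enumerate(points):
        g = (p - lo) / h
        i0 = np.clip(np.floor(g).astype(int), 0, np.array(shape) - 2)
        t = g - i0
        val = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = ((t[0] if dx else 1 - t[0])
                         * (t[1] if dy else 1 - t[1])
                         * (t[2] if dz else 1 - t[2]))
                    val += w * phi[i0[0] + dx, i0[1] + dy, i0[2] + dz]
        out[m] = val
    return out


def _coulomb_bc(axes, coords, charges, eps):
    """Analytic screened-Coulomb potential on all grid nodes."""
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    phi = np.zeros(X.shape)
    for c, q in zip(coords, charges):
        d = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
        d = np.maximum(d, 1e-6)
        phi += COULOMB * q / (eps * d)
    return phi


def _solve(axes, eps_nodes, q_nodes, phi_bc, tol, max_iter):
    """Solve div(eps grad phi) = -4 pi k rho with Dirichlet boundary."""
    h = axes[0][1] - axes[0][0]
    nx, ny, nz = eps_nodes.shape
    idx = -np.ones((nx, ny, nz), dtype=int)
    n_int = (nx - 2) * (ny - 2) * (nz - 2)
    idx[1:-1, 1:-1, 1:-1] = np.arange(n_int).reshape(nx - 2, ny - 2, nz - 2)
    I, J, K = np.where(idx >= 0)
    me = idx[I, J, K]
    diag = np.zeros(n_int)
    b = _FOUR_PI_K * q_nodes[I, J, K] / h
    rows, cols, vals = [me], [me], [None]
    inv_eps = 1.0 / eps_nodes
    for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                       (0, 0, 1), (0, 0, -1)):
        nI, nJ, nK = I + dx, J + dy, K + dz
        fe = 2.0 / (inv_eps[I, J, K] + inv_eps[nI, nJ, nK])
        diag += fe
        nid = idx[nI, nJ, nK]
        interior = nid >= 0
        rows.append(me[interior])
        cols.append(nid[interior])
        vals.append(-fe[interior])
        bmask = ~interior
        np.add.at(b, me[bmask], fe[bmask] * phi_bc[nI[bmask], nJ[bmask], nK[bmask]])
    vals[0] = diag
    A = coo_matrix((np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                   shape=(n_int, n_int)).tocsr()
    x0 = phi_bc[1:-1, 1:-1, 1:-1].ravel()
    x, info = cg(A, b, x0=x0, rtol=tol, maxiter=max_iter)
    if info != 0:
        residual = float(np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-30))
        raise PBConvergenceError(residual, max_iter)
    phi = phi_bc.copy()
    phi[1:-1, 1:-1, 1:-1] = x.reshape(nx - 2, ny - 2, nz - 2)
    return phi


def pb_energy(system: MolecularSystem, frame: np.ndarray,
              config: SolvationConfig | None = None,
              radii: np.ndarray | None = None,
              padding: float = 8.0) -> float:
    """Polar solvation free energy (kcal/mol) by two-stage focused FD-PB.

    Atom radii default to the GB intrinsic radii (falling back to LJ Rmin/2
    where unset); these define the solute dielectric envelope.
    """
    config = config or SolvationConfig(model="PB")
    frame = np.asarray(frame, float)
    coords = frame
    q = system.charges
    if not np.any(q):
        return 0.0
    if radii is None:
        radii = np.where(system.gb_radii > 0, system.gb_radii, system.rmin_half)
    radii = np.asarray(radii, float)
    if np.any(radii <= 0):
        raise ValueError("all atoms need positive radii for the PB dielectric map")
    h = config.pb_grid_spacing
    if h > 1.0:
        raise ValueError("pb_grid_spacing must be <= 1.0 A")
    if padding < 8.0:
        raise ValueError("grid padding must be >= 8 A")

    lo_f = coords.min(axis=0) - padding
    hi_f = coords.max(axis=0) + padding
    # --- coarse stage: Debye-Hueckel boundary, 4x spacing, wider box
    h_c = 4.0 * h
    lo_c = coords.min(axis=0) - (padding + 8.0)
    hi_c = coords.max(axis=0) + (padding + 8.0)
    axes_c = _grid_axes(lo_c, hi_c, h_c)
    eps_c = _node_dielectric(axes_c, coords, radii, config.eps_in, config.eps_out, h_c)
    q_c = _spread_charges(axes_c, coords, q)
    bc_c = _coulomb_bc(axes_c, coords, q, config.eps_out)
    phi_c = _solve(axes_c, eps_c, q_c, bc_c, config.pb_tolerance,
                   config.pb_max_iterations)

    # --- fine stage: boundary focused from the coarse solution
    axes_f = _grid_axes(lo_f, hi_f, h)
    eps_f = _node_dielectric(axes_f, coords, radii, config.eps_in, config.eps_out, h)
    q_f = _spread_charges(axes_f, coords, q)
    bc_f = np.zeros(tuple(len(a) for a in axes_f))
    bc_f_flat = _boundary_values(axes_f, axes_c, phi_c)
    bc_f[_boundary_mask(bc_f.shape)] = bc_f_flat
    phi_solv = _solve(axes_f, eps_f, q_f, bc_f, config.pb_tolerance,
                      config.pb_max_iterations)

    # --- uniform-dielectric reference on the identical fine grid
    eps_ref = np.full_like(eps_f, config.eps_in)
    bc_ref = _coulomb_bc(axes_f, coords, q, config.eps_in)
    phi_ref = _solve(axes_f, eps_ref, q_f, bc_ref, config.pb_tolerance,
                     config.pb_max_iterations)

    dphi = _interp(axes_f, phi_solv - phi_ref, coords)
    return float(0.5 * np.sum(q * dphi))


def _boundary_mask(shape):
    m = np.zeros(shape, bool)
    m[0, :, :] = m[-1, :, :] = True
    m[:, 0, :] = m[:, -1, :] = True
    m[:, :, 0] = m[:, :, -1] = True
    return m


def _boundary_values(axes_fine, axes_coarse, phi_coarse):
    shape = tuple(len(a) for a in axes_fine)
    mask = _boundary_mask(shape)
    I, J, K = np.where(mask)
    pts = np.stack([axes_fine[0][I], axes_fine[1][J], axes_fine[2][K]], axis=1)
    return _interp(axes_coarse, phi_coarse, pts)
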