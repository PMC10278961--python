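"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from bfekit.core import AtomRecord, Angle, Bond, MolecularSystem


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_atom(i, name="C1", element="C", resid=1, resname="UNK", chain="A",
              charge=0.0, rmh=1.7, eps=0.1, gbr=1.7, gbs=0.72):
    return AtomRecord(i, name, element, resid, resname, chain, charge,
                      rmh, eps, gbr, gbs)


@pytest.fixture
def diatomic():
    """C-O harmonic oscillator: k=300 kcal/mol/A^2, r0=1.2 A, no nonbonded."""
    atoms = [make_atom(0, "C", "C", eps=0.0), make_atom(1, "O", "O", eps=0.0, rmh=1.6)]
    system = MolecularSystem(atoms, bonds=[Bond(0, 1, 300.0, 1.2)])
    frame = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.25]])
    return system, frame


@pytest.fixture
def random_toy(rng):
    """10 random charged LJ atoms in a 6 A box, a few bonds/angles."""
    n = 10
    atoms = [make_atom(i, f"C{i}", "C", resid=1 + i // 3,
                       charge=float(rng.uniform(-0.5, 0.5)),
                       rmh=float(rng.uniform(1.4, 2.0)),
                       eps=float(rng.uniform(0.05, 0.2)),
                       gbr=float(rng.uniform(1.3, 2.0)),
                       gbs=float(rng.uniform(0.7, 0.9))) for i in range(n)]
    bonds = [Bond(i, i + 1, float(rng.uniform(200, 500)),
                  float(rng.uniform(1.2, 1.6))) for i in range(4)]
    angles = [Angle(i, i + 1, i + 2, float(rng.uniform(30, 80)),
                    float(rng.uniform(1.5, 2.5))) for i in range(3)]
    system = MolecularSystem(atoms, bonds, angles)
    # spread out enough that no interacting pair is coincident
    frame = rng.uniform(0, 6, size=(n, 3))
    while True:
        d = np.linalg.norm(frame[:, None] - frame[None, :], axis=-1)
        np.fill_diagonal(d, 9.9)
        if d.min() > 0.8:
            break
        frame = rng.uniform(0, 6, size=(n, 3))
    return system, frame


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_coulomb(system, frame, eps_in, group_a=None, group_b=None):
    """O(N^2) double loop, independent of the vectorized implementation."""
    k = 332.0637
    n = system.n_atoms
    ga = set(group_a) if group_a is not None else set(range(n))
    gb = set(group_b) if group_b is not None else set(range(n))
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if not ((i in ga and j in gb) or (j in ga and i in gb)):
                continue
            scale = system.exclusions.get((min(i, j), max(i, j)), (1.0, 1.0))[0]
            r = float(np.linalg.norm(frame[i] - frame[j]))
            total += scale * k * system.atoms[i].charge * system.atoms[j].charge / (eps_in * r)
    return total


def brute_force_lj(system, frame, group_a=None, group_b=None):
    n = system.n_atoms
    ga = set(group_a) if group_a is not None else set(range(n))
    gb = set(group_b) if group_b is not None else set(range(n))
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if not ((i in ga and j in gb) or (j in ga and i in gb)):
                continue
            scale = system.exclusions.get((min(i, j), max(i, j)), (1.0, 1.0))[1]
            r = float(np.linalg.norm(frame[i] - frame[j]))
            rmin = system.atoms[i].lj_rmin_half + system.atoms[j].lj_rmin_half
            eps = np.sqrt(system.atoms[i].lj_epsilon * system.atoms[j].lj_epsilon)
            x6 = (rmin / r) ** 6
            total += scale * eps * (x6 * x6 - 2 * x6)
    return total


def quaternion_rmsd(mobile, reference):
    """Kearsley quaternion method for the optimal-superposition RMSD."""
    x = np.asarray(mobile, float) - np.mean(mobile, axis=0)
    y = np.asarray(reference, float) - np.mean(reference, axis=0)
    sm = x - y
    sp = x + y
    K = np.zeros((4, 4))
    K[0, 0] = (sm ** 2).sum()
    K[1, 1] = (sm[:, 0] ** 2 + sp[:, 1] ** 2 + sp[:, 2] ** 2).sum()
    K[2, 2] = (sp[:, 0] ** 2 + sm[:, 1] ** 2 + sp[:, 2] ** 2).sum()
    K[3, 3] = (sp[:, 0] ** 2 + sp[:, 1] ** 2 + sm[:, 2] ** 2).sum()
    K[0, 1] = K[1, 0] = (sp[:, 1] * sm[:, 2] - sm[:, 1] * sp[:, 2]).sum()
    K[0, 2] = K[2, 0] = (sm[:, 0] * sp[:, 2] - sp[:, 0] * sm[:, 2]).sum()
    K[0, 3] = K[3, 0] = (sp[:, 0] * sm[:, 1] - sm[:, 0] * sp[:, 1]).sum()
    K[1, 2] = K[2, 1] = (sm[:, 0] * sm[:, 1] - sp[:, 0] * sp[:, 1]).sum()
    K[1, 3] = K[3, 1] = (sm[:, 0] * sm[:, 2] - sp[:, 0] * sp[:, 2]).sum()
    K[2, 3] = K[3, 2] = (sm[:, 1] * sm[:, 2] - sp[:, 1] * sp[:, 2]).sum()
    lam = np.linalg.eigvalsh(K)[0]
    return np.sqrt(max(lam, 0.0) / len(x))


def shrake_rupley_sasa(coords, radii, probe=1.4, n_points=2000):
    """Numeric SASA by golden-spiral surface points."""
    coords = np.asarray(coords, float)
    R = np.asarray(radii, float) + probe
    k = np.arange(n_points)
    phi = np.arccos(1 - 2 * (k + 0.5) / n_points)
    theta = np.pi * (1 + 5 ** 0.5) * k
    unit = np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)
    per_atom = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + R[i] * unit
        free = np.ones(n_points, bool)
        for j in range(len(coords)):
            if j == i:
                continue
            free &= np.linalg.norm(pts - coords[j], axis=1) >= R[j]
        per_atom[i] = 4 * np.pi * R[i] ** 2 * free.mean()
    return per_atom


def tetrahedral_chain(rng, n, bond=1.53, angle_deg=109.5, min_nb=2.8):
    """Self-avoiding chain with realistic bond angles and random dihedrals.

    This is the geometry regime the pairwise-overlap SASA parameterization
    was fit on; 1-2/1-3 distances are chemical, 1-4+ contacts are kept at
    nonbonded separation.
    """
    coords = [np.zeros(3), np.array([bond, 0.0, 0.0])]
    while len(coords) < n:
        prev, cur = coords[-2], coords[-1]
        for _ in range(200):
            u = cur - prev
            u = u / np.linalg.norm(u)
            r = rng.normal(size=3)
            r -= u * np.dot(r, u)
            r /= np.linalg.norm(r)
            theta = np.deg2rad(180 - angle_deg)
            cand = cur + bond * (np.cos(theta) * u + np.sin(theta) * r)
            far = coords[:-2]
            if not far or min(np.linalg.norm(cand - c) for c in far) >= min_nb:
                coords.append(cand)
                break
        else:
            break
    return np.array(coords)


def numeric_descreening_integral(r_ij, rho_i, s_j, n_r=400, n_t=400):
    """(1/4pi) int over sphere of radius s_j at distance r_ij of |x|^-4,
    excluding |x| < rho_i; Gauss-Legendre product quadrature."""
    xr, wr = np.polynomial.legendre.leggauss(n_r)
    xt, wt = np.polynomial.legendre.leggauss(n_t)
    r = 0.5 * s_j * (xr + 1)            # radius within sphere j
    wr = 0.5 * s_j * wr
    ct = xt                              # cos(theta)
    R2 = (r[:, None] ** 2 + r_ij ** 2 - 2 * r[:, None] * r_ij * ct[None, :])
    d = np.sqrt(R2)
    integrand = np.where(d >= rho_i, 1.0 / R2 ** 2, 0.0)
    vol = (r[:, None] ** 2 * integrand) * wr[:, None] * wt[None, :]
    return float(2 * np.pi * vol.sum() / (4 * np.pi))


def enumerate_simple_paths(edges, source, sink):
    """All simple paths with total weights, by exhaustive DFS."""
    adj = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    best = []

    def dfs(node, seen, weight, path):
        if node == sink:
            best.append((weight, list(path)))
            return
        for nxt, w in adj.get(node, []):
            if nxt not in seen:
                seen.add(nxt)
                path.append(nxt)
                dfs(nxt, seen, weight + w, path)
                path.pop()
                seen.remove(nxt)

    dfs(source, {source}, 0.0, [source])
    return best
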