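"""Core data model: atoms, molecular systems, trajectories, selection, superposition.

A :class:`MolecularSystem` carries the force-field parameters needed by the
downstream energy modules (partial charges, Lennard-Jones Rmin/2 + epsilon,
generalized-Born radii and screening factors, bonded terms) together with a
receptor/ligand partition.  Coordinates live in separate frames (``(N, 3)``
float arrays, Angstrom) so one parameterization can be evaluated over a whole
trajectory.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import ATOMIC_MASSES, SCEE, SCNB

__all__ = [
    "AtomRecord",
    "Bond",
    "Angle",
    "Dihedral",
    "MolecularSystem",
    "Trajectory",
    "select_atoms",
    "superpose",
    "kabsch",
]


@dataclass
class AtomRecord:
    """One atom with its nonbonded parameters.

    ``charge`` is in elementary charges, ``lj_rmin_half``/``gb_radius`` in
    Angstrom, ``lj_epsilon`` in kcal/mol.  ``gb_screen`` is the dimensionless
    descreening scale of the pairwise generalized-Born integral.
    """

    index: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    chain_id: str = "A"
    charge: float = 0.0
    lj_rmin_half: float = 0.0
    lj_epsilon: float = 0.0
    gb_radius: float = 0.0
    gb_screen: float = 0.0
    mass: float | None = None

    def __post_init__(self):
        if self.lj_epsilon < 0:
            raise ValueError(f"atom {self.index}: lj_epsilon must be >= 0")
        if self.mass is None:
            self.mass = ATOMIC_MASSES.get(self.element.upper(), 12.0)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Bond:
    i: int
    j: int
    k: float          # kcal/mol/A^2, E = k (r - r0)^2
    r0: float         # A


@dataclass
class Angle:
    i: int
    j: int
    k_atom: int
    k: float          # kcal/mol/rad^2, E = k (theta - theta0)^2
    theta0: float     # radians


@dataclass
class Dihedral:
    i: int
    j: int
    k_atom: int
    l: int
    vn: float         # barrier height V_n, kcal/mol; E = (V_n/2)(1 + cos(n phi - gamma))
    n: int
    gamma: float      # radians


class MolecularSystem:
    """Topology + parameters + receptor/ligand partition.

    Exclusions follow the AMBER convention: 1-2 and 1-3 pairs are fully
    excluded from nonbonded sums; 1-4 pairs are scaled (default 1/1.2
    electrostatic, 1/2 Lennard-Jones).  If no explicit exclusion table is
    given it is derived from the bond graph.
    """

    def __init__(self, atoms, bonds=(), angles=(), dihedrals=(),
                 exclusions=None, ligand_mask=None, receptor_mask=None):
        self.atoms: list[AtomRecord] = list(atoms)
        indices = [a.index for a in self.atoms]
        if len(set(indices)) != len(indices):
            raise ValueError("duplicate atom indices in system")
        if indices != list(range(len(indices))):
            raise ValueError("atom indices must be 0..N-1 in order")
        self.bonds: list[Bond] = list(bonds)
        self.angles: list[Angle] = list(angles)
        self.dihedrals: list[Dihedral] = list(dihedrals)
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) references invalid atom")
        for a in self.angles:
            if not all(0 <= x < n for x in (a.i, a.j, a.k_atom)):
                raise ValueError("angle references invalid atom")
        for d in self.dihedrals:
            if not all(0 <= x < n for x in (d.i, d.j, d.k_atom, d.l)):
                raise ValueError("dihedral references invalid atom")
        # exclusions: dict (i, j) i<j -> (ele_scale, vdw_scale)
        if exclusions is None:
            exclusions = self._derive_exclusions()
        self.exclusions: dict[tuple[int, int], tuple[float, float]] = dict(exclusions)
        self.ligand_mask: frozenset[int] = frozenset(ligand_mask or ())
        self.receptor_mask: frozenset[int] = frozenset(receptor_mask or ())
        if self.ligand_mask & self.receptor_mask:
            raise ValueError("ligand_mask and receptor_mask overlap")
        for idx in self.ligand_mask | self.receptor_mask:
            if not 0 <= idx < n:
                raise ValueError(f"mask references invalid atom {idx}")
        self._cache: dict[str, np.ndarray] = {}

    # -- parameter arrays ---------------------------------------------------
    def _arr(self, key, getter):
        if key not in self._cache:
            self._cache[key] = np.array([getter(a) for a in self.atoms], dtype=float)
        return self._cache[key]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def charges(self) -> np.ndarray:
        return self._arr("q", lambda a: a.charge)

    @property
    def rmin_half(self) -> np.ndarray:
        return self._arr("rmh", lambda a: a.lj_rmin_half)

    @property
    def epsilons(self) -> np.ndarray:
        return self._arr("eps", lambda a: a.lj_epsilon)

    @property
    def gb_radii(self) -> np.ndarray:
        return self._arr("gbr", lambda a: a.gb_radius)

    @property
    def gb_screens(self) -> np.ndarray:
        return self._arr("gbs", lambda a: a.gb_screen)

    @property
    def masses(self) -> np.ndarray:
        return self._arr("m", lambda a: a.mass)

    @property
    def heavy(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    def _derive_exclusions(self):
        """1-2/1-3 excluded, 1-4 scaled, from the bond graph."""
        n = len(self.atoms)
        adj = [set() for _ in range(n)]
        for b in self.bonds:
            adj[b.i].add(b.j)
            adj[b.j].add(b.i)
        excl = {}

        def put(i, j, scales):
            key = (min(i, j), max(i, j))
            if i == j:
                return
            # closer topological relations win (fully excluded < scaled)
            if key in excl and excl[key] == (0.0, 0.0):
                return
            excl[key] = scales

        for i in range(n):
            for j in adj[i]:
                put(i, j, (0.0, 0.0))
                for k in adj[j]:
                    if k == i:
                        continue
                    put(i, k, (0.0, 0.0))
                    for l in adj[k]:
                        if l in (i, j):
                            continue
                        put(i, l, (SCEE, SCNB))
        # 1-4 pairs that are also 1-2/1-3 via a ring stay excluded
        for i in range(n):
            for j in adj[i]:
                excl[(min(i, j), max(i, j))] = (0.0, 0.0)
                for k in adj[j]:
                    if k != i:
                        excl[(min(i, k), max(i, k))] = (0.0, 0.0)
        return excl

    def residue_ids(self) -> list[int]:
        """Distinct residue ids in order of first appearance."""
        seen, out = set(), []
        for a in self.atoms:
            if a.residue_id not in seen:
                seen.add(a.residue_id)
                out.append(a.residue_id)
        return out

    def residue_atoms(self, residue_id: int) -> list[int]:
        idx = [a.index for a in self.atoms if a.residue_id == residue_id]
        if not idx:
            raise KeyError(f"unknown residue id {residue_id}")
        return idx

    def subset(self, atom_indices) -> "MolecularSystem":
        """Extract a sub-system (renumbered 0..M-1); bonded terms fully
        inside the subset are kept, masks intersected."""
        keep = sorted(set(atom_indices))
        remap = {old: new for new, old in enumerate(keep)}
        atoms = []
        for new, old in enumerate(keep):
            a = self.atoms[old]
            atoms.append(AtomRecord(new, a.name, a.element, a.residue_id,
                                    a.residue_name, a.chain_id, a.charge,
                                    a.lj_rmin_half, a.lj_epsilon, a.gb_radius,
                                    a.gb_screen, a.mass))
        inside = lambda *ix: all(i in remap for i in ix)
        bonds = [Bond(remap[b.i], remap[b.j], b.k, b.r0)
                 for b in self.bonds if inside(b.i, b.j)]
        angles = [Angle(remap[a.i], remap[a.j], remap[a.k_atom], a.k, a.theta0)
                  for a in self.angles if inside(a.i, a.j, a.k_atom)]
        dihedrals = [Dihedral(remap[d.i], remap[d.j], remap[d.k_atom], remap[d.l],
                              d.vn, d.n, d.gamma)
                     for d in self.dihedrals if inside(d.i, d.j, d.k_atom, d.l)]
        excl = {(remap[i], remap[j]): s for (i, j), s in self.exclusions.items()
                if inside(i, j)}
        lig = [remap[i] for i in self.ligand_mask if i in remap]
        rec = [remap[i] for i in self.receptor_mask if i in remap]
        return MolecularSystem(atoms, bonds, angles, dihedrals, excl, lig, rec)


@dataclass
class Trajectory:
    """Ordered coordinate frames (Angstrom) over a fixed atom list."""

    frames: np.ndarray                  # (F, N, 3)
    frame_interval: float = 1.0         # ps, metadata only

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (F, N, 3)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates in trajectory")

    def __len__(self):
        return self.frames.shape[0]

    def __iter__(self):
        return iter(self.frames)

    @property
    def n_atoms(self):
        return self.frames.shape[1]


# ---------------------------------------------------------------------------
# atom selection
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(\(|\)|and\b|or\b|not\b|within\b|of\b|all\b|ligand\b|receptor\b|"
    r"resid\b|name\b|chain\b|[-\w.,*]+)", re.IGNORECASE)


def _tokenize(query: str):
    pos, tokens = 0, []
    while pos < len(query):
        m = _TOKEN_RE.match(query, pos)
        if not m:
            if query[pos:].strip():
                raise ValueError(f"cannot parse selection near {query[pos:]!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _SelParser:
    """Recursive-descent parser for the selection grammar:

    expr    := term {('or') term}
    term    := factor {('and') factor}
    factor  := 'not' factor | '(' expr ')' | primary
    primary := 'all' | 'ligand' | 'receptor'
             | 'resid' ranges | 'name' list | 'chain' list
             | 'within' NUMBER 'of' factor
    """

    def __init__(self, tokens, system, frame, whole_residues):
        self.tokens = tokens
        self.pos = 0
        self.system = system
        self.frame = frame
        self.whole_residues = whole_residues

    def peek(self):
        return self.tokens[self.pos].lower() if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self):
        out = self.expr()
        if self.pos != len(self.tokens):
            raise ValueError(f"trailing tokens in selection: {self.tokens[self.pos:]}")
        return out

    def expr(self):
        left = self.term()
        while self.peek() == "or":
            self.take()
            left = left | self.term()
        return left

    def term(self):
        left = self.factor()
        while self.peek() == "and":
            self.take()
            left = left & self.factor()
        return left

    def factor(self):
        tok = self.peek()
        if tok == "not":
            self.take()
            return set(range(self.system.n_atoms)) - self.factor()
        if tok == "(":
            self.take()
            inner = self.expr()
            if self.peek() != ")":
                raise ValueError("unbalanced parenthesis in selection")
            self.take()
            return inner
        return self.primary()

    def primary(self):
        tok = self.take().lower()
        sysm = self.system
        if tok == "all":
            return set(range(sysm.n_atoms))
        if tok == "ligand":
            return set(sysm.ligand_mask)
        if tok == "receptor":
            return set(sysm.receptor_mask)
        if tok == "resid":
            wanted = self._id_ranges(self.take())
            known = set(a.residue_id for a in sysm.atoms)
            missing = wanted - known
            if missing:
                raise ValueError(f"unknown residue id(s) {sorted(missing)}")
            return {a.index for a in sysm.atoms if a.residue_id in wanted}
        if tok == "name":
            names = {s.upper() for s in self.take().split(",")}
            return {a.index for a in sysm.atoms if a.name.upper() in names}
        if tok == "chain":
            chains = {s.upper() for s in self.take().split(",")}
            return {a.index for a in sysm.atoms if a.chain_id.upper() in chains}
        if tok == "within":
            radius_tok = self.take()
            radius = np.inf if radius_tok.lower() in ("inf", "infinity") else float(radius_tok)
            if self.peek() != "of":
                raise ValueError("'within R' must be followed by 'of <selection>'")
            self.take()
            ref = self.factor()
            return self._within(radius, ref)
        raise ValueError(f"unknown selection token {tok!r}")

    @staticmethod
    def _id_ranges(spec: str) -> set[int]:
        out = set()
        for part in spec.split(","):
            if "-" in part[1:]:  # allow leading minus
                lo, hi = part.rsplit("-", 1) if not part.startswith("-") else (part, part)
                out.update(range(int(lo), int(hi) + 1))
            else:
                out.add(int(part))
        return out

    def _within(self, radius, ref_set):
        """Heavy atoms within ``radius`` of any heavy atom of ``ref_set``."""
        if self.frame is None:
            raise ValueError("'within' selection requires coordinates")
        if np.isinf(radius):
            return set(range(self.system.n_atoms))
        heavy = self.system.heavy
        ref = [i for i in sorted(ref_set) if heavy[i]]
        if not ref:
            return set()
        cand = np.where(heavy)[0]
        ref_xyz = self.frame[ref]
        d = np.linalg.norm(self.frame[cand][:, None, :] - ref_xyz[None, :, :], axis=-1)
        hit = cand[(d <= radius).any(axis=1)]
        out = set(int(i) for i in hit)
        if self.whole_residues:
            res_hit = {self.system.atoms[i].residue_id for i in out}
            out = {a.index for a in self.system.atoms if a.residue_id in res_hit}
        return out


def select_atoms(system: MolecularSystem, query: str, frame: np.ndarray | None = None,
                 whole_residues: bool = False) -> set[int]:
    """Evaluate a selection query against a system (and frame, for distances).

    Grammar: ``all | ligand | receptor | resid 3,5-9 | name CA,CB | chain A |
    within R of <sel>`` combined with ``and``, ``or``, ``not`` and parentheses.
    ``within`` measures heavy-atom/heavy-atom distances; with
    ``whole_residues=True`` a residue with any heavy atom inside the cutoff is
    selected whole.
    """
    tokens = _tokenize(query)
    if not tokens:
        raise ValueError("empty selection query")
    return _SelParser(tokens, system, frame, whole_residues).parse()


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray, weights=None):
    """Optimal rotation/translation of ``mobile`` onto ``reference``.

    Returns ``(rotation (3,3), translation (3,), rmsd)`` minimising the
    weighted least-squares deviation over the given point sets.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2:
        raise ValueError("point sets must have identical (N, 3) shapes")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 fit atoms")
    w = np.ones(len(mobile)) if weights is None else np.asarray(weights, float)
    mc = np.average(mobile, axis=0, weights=w)
    rc = np.average(reference, axis=0, weights=w)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc, weights=w)
    R = rot.as_matrix()
    t = rc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.average(np.sum((moved - reference) ** 2, axis=1), weights=w)))
    return R, t, rmsd


def superpose(mobile_frame: np.ndarray, reference_frame: np.ndarray,
              fit_set=None):
    """Least-squares superpose a whole frame using ``fit_set`` atoms.

    Returns ``(fitted_frame, rmsd_over_fit_set)``.
    """
    mobile_frame = np.asarray(mobile_frame, float)
    reference_frame = np.asarray(reference_frame, float)
    if fit_set is None:
        fit = np.arange(mobile_frame.shape[0])
    else:
        fit = np.array(sorted(fit_set), dtype=int)
    if fit.size < 3:
        raise ValueError("superposition needs at least 3 fit atoms")
    sub_m = mobile_frame[fit]
    sub_r = reference_frame[fit]
    # collinearity check: rank of centered coordinates must exceed 1
    if np.linalg.matrix_rank(sub_m - sub_m.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("fit atoms are collinear; superposition is degenerate")
    R, t, rmsd = kabsch(sub_m, sub_r)
    return mobile_frame @ R.T + t, rmsd
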