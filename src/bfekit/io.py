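"""File formats.

* PDB (``ATOM``/``HETATM``; ``MODEL``/``ENDMDL`` for trajectories) for
  structures and multi-model trajectories.
* A plain-text toy topology carrying all force-field parameters, with
  sections ``[atoms] [bonds] [angles] [dihedrals] [exclusions] [masks]``
  (schema in :func:`read_toy_topology`).
* Whitespace xyz tables for trajectories, two-column text tables for
  umbrella-window samples and per-lambda dU/dlambda series.

All readers tolerate blank lines and ``#`` comments.
"""

from __future__ import annotations

import math
import os

import numpy as np

from .core import AtomRecord, Angle, Bond, Dihedral, MolecularSystem, Trajectory

__all__ = [
    "read_pdb", "write_pdb", "read_pdb_trajectory", "write_pdb_trajectory",
    "read_toy_topology", "write_toy_topology",
    "read_xyz_table", "write_xyz_table",
    "read_series", "write_series",
]


class ParseError(ValueError):
    """Malformed input file; message carries file and line number."""


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int, path) -> tuple[AtomRecord, np.ndarray]:
    try:
        name = line[12:16].strip()
        resname = line[17:20].strip() or "UNK"
        chain = line[21].strip() or "A"
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = "".join(c for c in name if c.isalpha())[:1] or "C"
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}:{lineno}: malformed ATOM/HETATM record: {exc}") from exc
    rec = AtomRecord(0, name, element, resid, resname, chain)
    return rec, np.array([x, y, z])


def read_pdb(path):
    """Read a PDB file -> ``(MolecularSystem skeleton, frame)``.

    Only ATOM/HETATM records of the first MODEL are used; force-field fields
    are left unset (zero).  Raises :class:`ParseError` naming the offending
    line for malformed records, and on files with no atoms.
    """
    atoms, coords = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6].strip()
            if tag in ("ATOM", "HETATM"):
                rec, xyz = _parse_atom_line(line, lineno, path)
                rec.index = len(atoms)
                atoms.append(rec)
                coords.append(xyz)
            elif tag == "ENDMDL":
                break
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records (empty system)")
    return MolecularSystem(atoms), np.array(coords)


def _format_atom_line(i, atom, xyz, hetatm=False):
    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
    return (f"{'HETATM' if hetatm else 'ATOM  '}{i + 1:5d} {name:<4.4s} "
            f"{atom.residue_name:<3.3s} {atom.chain_id:1.1s}{atom.residue_id:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {atom.element:>2.2s}\n")


def write_pdb(path, system: MolecularSystem, frame: np.ndarray):
    frame = np.asarray(frame, float)
    if frame.shape != (system.n_atoms, 3):
        raise ValueError("frame shape does not match system atom count")
    with open(path, "w") as fh:
        for i, atom in enumerate(system.atoms):
            fh.write(_format_atom_line(i, atom, frame[i], hetatm=i in system.ligand_mask))
        fh.write("END\n")


def read_pdb_trajectory(path) -> tuple[MolecularSystem, Trajectory]:
    """Read a multi-model PDB into a system skeleton + trajectory."""
    frames, atoms, cur = [], [], []
    first_model = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6].strip()
            if tag in ("ATOM", "HETATM"):
                rec, xyz = _parse_atom_line(line, lineno, path)
                if first_model:
                    rec.index = len(atoms)
                    atoms.append(rec)
                cur.append(xyz)
            elif tag == "ENDMDL":
                if cur:
                    frames.append(np.array(cur))
                    cur = []
                    first_model = False
    if cur:
        frames.append(np.array(cur))
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records (empty system)")
    n = len(atoms)
    for k, f in enumerate(frames):
        if f.shape[0] != n:
            raise ParseError(f"{path}: MODEL {k + 1} has {f.shape[0]} atoms, expected {n}")
    return MolecularSystem(atoms), Trajectory(np.array(frames))


def write_pdb_trajectory(path, system: MolecularSystem, trajectory: Trajectory):
    with open(path, "w") as fh:
        for m, frame in enumerate(trajectory, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, atom in enumerate(system.atoms):
                fh.write(_format_atom_line(i, atom, frame[i],
                                           hetatm=i in system.ligand_mask))
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# toy topology
# ---------------------------------------------------------------------------

_SECTIONS = ("atoms", "bonds", "angles", "dihedrals", "exclusions", "masks")


def read_toy_topology(path) -> MolecularSystem:
    """Read the plain-text toy topology format.

    ::

        [atoms]
        # index name element resid resname chain charge rmin_half epsilon gb_radius gb_screen [mass]
        0 C1 C 1 LIG L -0.10 1.908 0.1094 1.70 0.72
        [bonds]
        # i j k r0          (E = k (r-r0)^2)
        0 1 300.0 1.50
        [angles]
        # i j k ktheta theta0_deg   (E = k (theta-theta0)^2)
        [dihedrals]
        # i j k l vn periodicity gamma_deg   (E = (vn/2)(1+cos(n phi - gamma)))
        [exclusions]
        # i j ele_scale vdw_scale   (0 0 = fully excluded; omit section to
        #                            derive 1-2/1-3 exclusion + 1-4 scaling
        #                            from the bond graph)
        [masks]
        ligand 0-4
        receptor 5,6,8-20

    Angles in degrees on disk, radians in memory.
    """
    sections: dict[str, list[tuple[int, str]]] = {s: [] for s in _SECTIONS}
    current = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1].strip().lower()
                if current not in _SECTIONS:
                    raise ParseError(f"{path}:{lineno}: unknown section [{current}]")
                continue
            if current is None:
                raise ParseError(f"{path}:{lineno}: data before any section header")
            sections[current].append((lineno, line))

    atoms = []
    for lineno, line in sections["atoms"]:
        parts = line.split()
        if len(parts) not in (11, 12):
            raise ParseError(
                f"{path}:{lineno}: atom line needs 11 or 12 fields "
                f"(index name element resid resname chain charge rmin_half "
                f"epsilon gb_radius gb_screen [mass]), got {len(parts)}")
        try:
            atoms.append(AtomRecord(
                index=int(parts[0]), name=parts[1], element=parts[2],
                residue_id=int(parts[3]), residue_name=parts[4], chain_id=parts[5],
                charge=float(parts[6]), lj_rmin_half=float(parts[7]),
                lj_epsilon=float(parts[8]), gb_radius=float(parts[9]),
                gb_screen=float(parts[10]),
                mass=float(parts[11]) if len(parts) == 12 else None))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc

    def tuple_rows(name, nfields):
        rows = []
        for lineno, line in sections[name]:
            parts = line.split()
            if len(parts) != nfields:
                raise ParseError(f"{path}:{lineno}: [{name}] line needs "
                                 f"{nfields} fields, got {len(parts)}")
            rows.append((lineno, parts))
        return rows

    bonds = [Bond(int(p[0]), int(p[1]), float(p[2]), float(p[3]))
             for _, p in tuple_rows("bonds", 4)]
    angles = [Angle(int(p[0]), int(p[1]), int(p[2]), float(p[3]),
                    math.radians(float(p[4])))
              for _, p in tuple_rows("angles", 5)]
    dihedrals = [Dihedral(int(p[0]), int(p[1]), int(p[2]), int(p[3]),
                          float(p[4]), int(p[5]), math.radians(float(p[6])))
                 for _, p in tuple_rows("dihedrals", 7)]
    exclusions = None
    if sections["exclusions"]:
        exclusions = {}
        for _, p in tuple_rows("exclusions", 4):
            i, j = int(p[0]), int(p[1])
            exclusions[(min(i, j), max(i, j))] = (float(p[2]), float(p[3]))

    masks = {"ligand": [], "receptor": []}
    for lineno, line in sections["masks"]:
        parts = line.split(None, 1)
        if len(parts) != 2 or parts[0].lower() not in masks:
            raise ParseError(f"{path}:{lineno}: mask line must be "
                             f"'ligand <ids>' or 'receptor <ids>'")
        ids = set()
        for chunk in parts[1].replace(",", " ").split():
            if "-" in chunk[1:]:
                lo, hi = chunk.rsplit("-", 1)
                ids.update(range(int(lo), int(hi) + 1))
            else:
                ids.add(int(chunk))
        masks[parts[0].lower()] = sorted(ids)

    try:
        system = MolecularSystem(atoms, bonds, angles, dihedrals, exclusions,
                                 masks["ligand"], masks["receptor"])
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    _validate_parameters(system, path)
    return system


def _validate_parameters(system, path):
    bad = [a.index for a in system.atoms
           if not all(np.isfinite([a.charge, a.lj_rmin_half, a.lj_epsilon,
                                   a.gb_radius, a.gb_screen]))]
    if bad:
        raise ParseError(f"{path}: atoms {bad} have missing/non-finite parameters")


def write_toy_topology(path, system: MolecularSystem):
    with open(path, "w") as fh:
        fh.write("# toy topology\n[atoms]\n")
        fh.write("# index name element resid resname chain charge rmin_half"
                 " epsilon gb_radius gb_screen mass\n")
        for a in system.atoms:
            fh.write(f"{a.index} {a.name} {a.element} {a.residue_id} "
                     f"{a.residue_name} {a.chain_id} {a.charge:.10g} "
                     f"{a.lj_rmin_half:.10g} {a.lj_epsilon:.10g} "
                     f"{a.gb_radius:.10g} {a.gb_screen:.10g} {a.mass:.10g}\n")
        fh.write("[bonds]\n")
        for b in system.bonds:
            fh.write(f"{b.i} {b.j} {b.k:.10g} {b.r0:.10g}\n")
        fh.write("[angles]\n")
        for a in system.angles:
            fh.write(f"{a.i} {a.j} {a.k_atom} {a.k:.10g} "
                     f"{math.degrees(a.theta0):.10g}\n")
        fh.write("[dihedrals]\n")
        for d in system.dihedrals:
            fh.write(f"{d.i} {d.j} {d.k_atom} {d.l} {d.vn:.10g} {d.n} "
                     f"{math.degrees(d.gamma):.10g}\n")
        fh.write("[exclusions]\n")
        for (i, j), (se, sv) in sorted(system.exclusions.items()):
            fh.write(f"{i} {j} {se:.10g} {sv:.10g}\n")
        fh.write("[masks]\n")
        if system.ligand_mask:
            fh.write("ligand " + ",".join(map(str, sorted(system.ligand_mask))) + "\n")
        if system.receptor_mask:
            fh.write("receptor " + ",".join(map(str, sorted(system.receptor_mask))) + "\n")


# ---------------------------------------------------------------------------
# plain tables
# ---------------------------------------------------------------------------

def read_xyz_table(path, n_atoms: int) -> Trajectory:
    """Whitespace table with one row per atom (x y z), frames concatenated."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] != 3 or data.shape[0] % n_atoms:
        raise ParseError(f"{path}: expected rows of 3 columns in multiples of "
                         f"{n_atoms}, got shape {data.shape}")
    return Trajectory(data.reshape(-1, n_atoms, 3))


def write_xyz_table(path, trajectory: Trajectory):
    with open(path, "w") as fh:
        fh.write("# x y z; frames concatenated\n")
        for frame in trajectory:
            np.savetxt(fh, frame, fmt="%.6f")


def read_series(path) -> np.ndarray:
    """Two-column text (index, value) or one-column values -> value array."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] == 1:
        return data[:, 0]
    return data[:, 1]


def write_series(path, values, header=""):
    values = np.asarray(values, float)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for i, v in enumerate(values):
            fh.write(f"{i} {v:.10g}\n")
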