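"""Structures, trajectories, PDB input/output, and atom selections.

:class:`Structure` wraps a ``biotite`` :class:`~biotite.structure.AtomArray`
(one coordinate set), :class:`Trajectory` an
:class:`~biotite.structure.AtomArrayStack` (many frames sharing one atom
table, e.g. a multi-model PDB).  File handling is delegated to biotite's
fixed-column PDB reader/writer; this module adds the policies used
throughout the analyses:

* altloc: keep the highest-occupancy conformer (ties resolve to the
  first, i.e. 'A' under standard ordering);
* hydrogens dropped by default, HETATM (ions, lipids, water) retained;
* atoms across two structures are matched by (chain id, residue id,
  atom name), and unmatched atoms are an error, never a silent drop.

Selections use a small boolean expression grammar over per-atom fields::

    expr     := term  { "or" term }
    term     := factor { "and" factor }
    factor   := "not" factor | "(" expr ")" | primitive
    primitive:= "chain" IDS | "resid" RANGES | "name" IDS
              | "resname" IDS | "element" IDS | "hetero" | "all"
    RANGES   := N | N "-" M { "," RANGES }
    IDS      := token { "," token }

e.g. ``"chain A and resid 124-235 and name CA"`` or
``"resname ARG,LYS and not name CA"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Structure",
    "Trajectory",
    "read_pdb",
    "read_pdb_trajectory",
    "write_pdb",
    "write_pdb_trajectory",
    "SelectionError",
    "matched_coords",
]


class SelectionError(ValueError):
    """A selection expression that cannot be parsed or resolves badly."""


# ---------------------------------------------------------------------------
# selection grammar
# ---------------------------------------------------------------------------

def _tokenize(expr: str) -> List[str]:
    out: List[str] = []
    for raw in expr.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


def _parse_ranges(tok: str) -> List[Tuple[int, int]]:
    ranges = []
    for part in tok.split(","):
        if "-" in part[1:]:  # allow negative single ids
            cut = part.index("-", 1)
            lo, hi = int(part[:cut]), int(part[cut + 1:])
        else:
            lo = hi = int(part)
        if hi < lo:
            raise SelectionError(f"bad residue range {part!r}")
        ranges.append((lo, hi))
    return ranges


class _Parser:
    def __init__(self, tokens: List[str], atoms: struc.AtomArray):
        self.toks = tokens
        self.i = 0
        self.atoms = atoms

    def peek(self):
        return self.toks[self.i] if self.i < len(self.toks) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection")
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens at {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.primitive()

    def primitive(self) -> np.ndarray:
        tok = self.next()
        a = self.atoms
        if tok == "all":
            return np.ones(a.array_length(), dtype=bool)
        if tok == "hetero":
            return np.asarray(a.hetero)
        if tok == "chain":
            ids = self.next().split(",")
            return np.isin(a.chain_id, ids)
        if tok == "name":
            ids = self.next().split(",")
            return np.isin(a.atom_name, ids)
        if tok == "resname":
            ids = self.next().split(",")
            return np.isin(a.res_name, ids)
        if tok == "element":
            ids = [s.upper() for s in self.next().split(",")]
            return np.isin(np.char.upper(np.asarray(a.element)), ids)
        if tok == "resid":
            mask = np.zeros(a.array_length(), dtype=bool)
            for lo, hi in _parse_ranges(self.next()):
                mask |= (a.res_id >= lo) & (a.res_id <= hi)
            return mask
        raise SelectionError(f"unknown selection token {tok!r}")


def _selection_mask(atoms: struc.AtomArray, expr: str) -> np.ndarray:
    if not expr or not expr.strip():
        raise SelectionError("empty selection expression")
    return _Parser(_tokenize(expr), atoms).parse()


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Structure:
    """A single labeled 3D coordinate set (PDB-compatible)."""

    atoms: struc.AtomArray

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.atoms.coord)

    @coords.setter
    def coords(self, value: np.ndarray) -> None:
        self.atoms.coord = np.asarray(value, dtype=np.float32).reshape(self.n_atoms, 3)

    def select(self, expr: str) -> "Structure":
        mask = _selection_mask(self.atoms, expr)
        if not mask.any():
            raise SelectionError(f"selection {expr!r} matches no atoms")
        return Structure(self.atoms[mask])

    def mask(self, expr: str) -> np.ndarray:
        return _selection_mask(self.atoms, expr)

    def atom_keys(self) -> List[Tuple[str, int, str]]:
        """(chain id, residue id, atom name) key per atom, in order."""
        a = self.atoms
        return list(zip(a.chain_id.tolist(), a.res_id.tolist(), a.atom_name.tolist()))

    def copy(self) -> "Structure":
        return Structure(self.atoms.copy())


@dataclass
class Trajectory:
    """Frames sharing one atom table."""

    frames: struc.AtomArrayStack

    @property
    def n_frames(self) -> int:
        return self.frames.stack_depth()

    @property
    def n_atoms(self) -> int:
        return self.frames.array_length()

    @property
    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate array."""
        return np.asarray(self.frames.coord)

    def frame(self, i: int) -> Structure:
        return Structure(self.frames[i])

    def mask(self, expr: str) -> np.ndarray:
        return _selection_mask(self.frames[0], expr)

    def select(self, expr: str) -> "Trajectory":
        mask = self.mask(expr)
        if not mask.any():
            raise SelectionError(f"selection {expr!r} matches no atoms")
        return Trajectory(self.frames[:, mask])

    @classmethod
    def from_structures(cls, structures: Sequence[Structure]) -> "Trajectory":
        return cls(struc.stack([s.atoms for s in structures]))


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------


def _load(path, model=None, keep_hydrogens=False):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=model, altloc="occupancy")
    except Exception as exc:  # biotite reports the offending line
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    if atoms.array_length() == 0:
        raise ValueError(f"no ATOM/HETATM records in {path}")
    if not keep_hydrogens:
        element = np.char.upper(np.asarray(atoms.element))
        mask = element != "H"
        atoms = atoms[..., mask] if isinstance(atoms, struc.AtomArrayStack) else atoms[mask]
    return atoms


def read_pdb(path, keep_hydrogens: bool = False) -> Structure:
    """Read the first model of a PDB file (fixed-column dialect)."""
    return Structure(_load(path, model=1, keep_hydrogens=keep_hydrogens))


def read_pdb_trajectory(path, keep_hydrogens: bool = False) -> Trajectory:
    """Read all models of a multi-model PDB file as a trajectory."""
    atoms = _load(path, model=None, keep_hydrogens=keep_hydrogens)
    if isinstance(atoms, struc.AtomArray):
        atoms = struc.stack([atoms])
    return Trajectory(atoms)


def write_pdb(structure: Structure, path) -> None:
    pdb = PDBFile()
    pdb.set_structure(structure.atoms)
    pdb.write(str(path))


def write_pdb_trajectory(trajectory: Trajectory, path) -> None:
    pdb = PDBFile()
    pdb.set_structure(trajectory.frames)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# cross-structure matching
# ---------------------------------------------------------------------------


def matched_coords(
    a: Structure,
    b: Structure,
    selection: str = "all",
) -> Tuple[np.ndarray, np.ndarray]:
    """Coordinates of selection atoms matched across two structures.

    Atoms are paired by (chain id, residue id, atom name); an atom present
    in only one structure raises, listing the offenders.
    """
    sa, sb = a.select(selection), b.select(selection)
    ka, kb = sa.atom_keys(), sb.atom_keys()
    set_a, set_b = set(ka), set(kb)
    if len(set_a) != len(ka) or len(set_b) != len(kb):
        raise SelectionError("duplicate (chain, resid, atom name) keys in selection")
    missing = set_a.symmetric_difference(set_b)
    if missing:
        listed = ", ".join(f"{c}/{r}/{n}" for c, r, n in sorted(missing)[:10])
        raise SelectionError(
            f"{len(missing)} unmatched atoms between structures: {listed}"
        )
    idx_b = {k: i for i, k in enumerate(kb)}
    order = [idx_b[k] for k in ka]
    return sa.coords, sb.coords[order]
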