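"""Structure/trajectory containers, multi-model PDB I/O, atom selection,
and interaction-label formatting.

Coordinates are stored in nanometres throughout (PDB files are in
ångström and converted on read/write); times are in picoseconds.
Residue numbering is the 1-based author numbering of the input and is
never remapped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import PDBParseError, SelectionError, StructureError
from .templates import one_letter

ANGSTROM_PER_NM = 10.0


@dataclass(frozen=True)
class Atom:
    """One atom of the (frame-invariant) atom table."""

    serial: int
    name: str
    residue_name: str
    residue_number: int
    chain_id: str = "A"
    element: str = ""

    def __post_init__(self):
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.residue_number < 1:
            raise ValueError("residue_number must be >= 1")
        if self.serial < 1:
            raise ValueError("serial must be positive")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.name)


@dataclass(frozen=True)
class Frame:
    """One time point: an (n_atoms, 3) coordinate array in nm."""

    index: int
    time: float  # ps
    coordinates: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        object.__setattr__(self, "coordinates", coords)
        if self.time < 0:
            raise ValueError("frame time must be >= 0 ps")


class Trajectory:
    """An ordered stack of frames sharing one atom table.

    Internally the coordinates live in a single ``(n_frames, n_atoms, 3)``
    float array so distance/angle operations can be vectorised.
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        coordinates: np.ndarray,
        times: Sequence[float] | None = None,
        frame_spacing: float = 10.0,
    ):
        self.atoms: tuple[Atom, ...] = tuple(atoms)
        coords = np.asarray(coordinates, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if coords.shape[0] < 1:
            raise StructureError("a trajectory needs at least one frame")
        if coords.shape[1] != len(self.atoms):
            raise StructureError(
                f"coordinate count ({coords.shape[1]}) does not match "
                f"atom count ({len(self.atoms)})"
            )
        seen: set[tuple[str, int, str]] = set()
        for atom in self.atoms:
            if atom.key in seen:
                raise StructureError(f"duplicate atom {atom.key} in atom table")
            seen.add(atom.key)
        self.coordinates = coords
        self.frame_spacing = float(frame_spacing)
        if times is None:
            times = np.arange(coords.shape[0], dtype=float) * self.frame_spacing
        self.times = np.asarray(times, dtype=float)
        if self.times.shape != (coords.shape[0],):
            raise ValueError("times must have one entry per frame")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    # -- basic container protocol -------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Frame:
        return Frame(index=i, time=float(self.times[i]), coordinates=self.coordinates[i])

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)

    # -- lookups -------------------------------------------------------
    def atom_index(self, residue_number: int, name: str, chain_id: str | None = None) -> int:
        for i, a in enumerate(self.atoms):
            if a.residue_number == residue_number and a.name == name:
                if chain_id is None or a.chain_id == chain_id:
                    return i
        raise SelectionError(
            f"no atom named {name!r} in residue {residue_number}"
            + (f" chain {chain_id}" if chain_id else "")
        )

    def residue_numbers(self) -> list[int]:
        out: list[int] = []
        for a in self.atoms:
            if not out or a.residue_number != out[-1]:
                if a.residue_number not in out:
                    out.append(a.residue_number)
        return out

    def residue_name(self, residue_number: int) -> str:
        for a in self.atoms:
            if a.residue_number == residue_number:
                return a.residue_name
        raise SelectionError(f"no residue numbered {residue_number}")


@dataclass(frozen=True)
class Selection:
    """A resolved atom selection; index order follows the atom table."""

    expression: str
    resolved_atoms: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.resolved_atoms)


# ---------------------------------------------------------------------------
# Selection mini-language
#
# Grammar: clause ("and" clause)* where each clause is one of
#   resid   N [N ...]     residue numbers
#   resname XXX [XXX ...] residue 3-letter codes
#   name    A [A ...]     atom names
#   chain   C [C ...]     chain ids
# Resolution is a conjunction over clauses, a disjunction within a clause.

_CLAUSE_KEYWORDS = ("resid", "resname", "name", "chain")


def select(traj: Trajectory, expression: str) -> Selection:
    """Resolve a selection expression against a trajectory's atom table.

    Deterministic: a pure function of the atom table and the expression.
    Raises :class:`SelectionError` if the expression is malformed or
    resolves to no atoms.
    """
    tokens = expression.split()
    if not tokens:
        raise SelectionError("empty selection expression")
    clauses: list[tuple[str, list[str]]] = []
    current: tuple[str, list[str]] | None = None
    for tok in tokens:
        if tok == "and":
            if current is None:
                raise SelectionError(f"misplaced 'and' in {expression!r}")
            current = None
            continue
        if current is None:
            if tok not in _CLAUSE_KEYWORDS:
                raise SelectionError(
                    f"expected one of {_CLAUSE_KEYWORDS}, got {tok!r} in {expression!r}"
                )
            current = (tok, [])
            clauses.append(current)
        else:
            current[1].append(tok)
    for kw, values in clauses:
        if not values:
            raise SelectionError(f"clause {kw!r} has no values in {expression!r}")
        if kw == "resid":
            for v in values:
                if not v.lstrip("-").isdigit():
                    raise SelectionError(f"non-integer resid {v!r} in {expression!r}")

    def matches(atom: Atom) -> bool:
        for kw, values in clauses:
            if kw == "resid" and atom.residue_number not in [int(v) for v in values]:
                return False
            if kw == "resname" and atom.residue_name.upper() not in [v.upper() for v in values]:
                return False
            if kw == "name" and atom.name.upper() not in [v.upper() for v in values]:
                return False
            if kw == "chain" and atom.chain_id not in values:
                return False
        return True

    resolved = tuple(i for i, a in enumerate(traj.atoms) if matches(a))
    if not resolved:
        raise SelectionError(f"selection {expression!r} resolved to no atoms")
    return Selection(expression=expression, resolved_atoms=resolved)


# ---------------------------------------------------------------------------
# Multi-model PDB

def _parse_atom_record(line: str, line_number: int) -> tuple[Atom, tuple[float, float, float]]:
    # PDB fixed columns (1-based): serial 7-11, name 13-16, resName 18-20,
    # chainID 22, resSeq 23-26, x 31-38, y 39-46, z 47-54, element 77-78.
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError("ATOM record shorter than the coordinate fields", line_number)
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        residue_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"malformed ATOM record ({exc})", line_number) from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = name[:1]
    try:
        atom = Atom(
            serial=serial,
            name=name,
            residue_name=residue_name,
            residue_number=residue_number,
            chain_id=chain_id,
            element=element,
        )
    except ValueError as exc:
        raise PDBParseError(str(exc), line_number) from None
    return atom, (x / ANGSTROM_PER_NM, y / ANGSTROM_PER_NM, z / ANGSTROM_PER_NM)


def read_multimodel_pdb(path: str | Path, frame_spacing: float = 10.0) -> Trajectory:
    """Read a (multi-)model PDB file into a :class:`Trajectory`.

    One frame per MODEL (a bare ATOM block yields a single frame);
    coordinates converted Å → nm.  The atom table is taken from the first
    model; later models must present the same atoms in the same order.
    """
    path = Path(path)
    models: list[list[tuple[Atom, tuple[float, float, float]]]] = []
    current: list[tuple[Atom, tuple[float, float, float]]] | None = None
    saw_model_kw = False
    with path.open() as handle:
        for line_number, line in enumerate(handle, start=1):
            record = line[:6].strip()
            if record == "MODEL":
                saw_model_kw = True
                if current:
                    models.append(current)
                current = []
            elif record == "ENDMDL":
                if current is not None:
                    models.append(current)
                current = None
            elif record in ("ATOM", "HETATM"):
                if current is None:
                    if saw_model_kw and models:
                        raise PDBParseError("ATOM record outside MODEL block", line_number)
                    current = []
                current.append(_parse_atom_record(line, line_number))
    if current:
        models.append(current)
    if not models:
        raise PDBParseError(f"{path}: no ATOM records found")

    atoms = tuple(a for a, _ in models[0])
    n_atoms = len(atoms)
    coords = np.empty((len(models), n_atoms, 3), dtype=float)
    for m, model in enumerate(models):
        if len(model) != n_atoms:
            raise StructureError(
                f"model {m + 1} has {len(model)} atoms, expected {n_atoms}"
            )
        for i, (atom, xyz) in enumerate(model):
            if atom.key != atoms[i].key:
                raise StructureError(
                    f"model {m + 1} atom {i + 1} is {atom.key}, expected {atoms[i].key}"
                )
            coords[m, i] = xyz
    return Trajectory(atoms=atoms, coordinates=coords, frame_spacing=frame_spacing)


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (nm → Å, %8.3f precision)."""
    path = Path(path)
    with path.open("w") as handle:
        for f in range(traj.n_frames):
            handle.write(f"MODEL     {f + 1:4d}\n")
            for i, atom in enumerate(traj.atoms):
                x, y, z = traj.coordinates[f, i] * ANGSTROM_PER_NM
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                handle.write(
                    f"ATOM  {atom.serial:5d} {name:<4s} {atom.residue_name:>3s} "
                    f"{atom.chain_id}{atom.residue_number:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{atom.element:>2s}\n"
                )
            handle.write("ENDMDL\n")
        handle.write("END\n")


# ---------------------------------------------------------------------------
# Interaction labels

#: atom-context markers used in interaction labels
SIDECHAIN_CTX = ""
BACKBONE_O_CTX = "(O)"
BACKBONE_NH_CTX = "(NH)"
_VALID_CTX = (SIDECHAIN_CTX, BACKBONE_O_CTX, BACKBONE_NH_CTX)


def format_interaction_label(
    res_a: tuple[str, int],
    atom_context_a: str,
    res_b: tuple[str, int],
    atom_context_b: str,
) -> str:
    """Format a residue-pair label like ``"V37(O):A40(NH)"``.

    ``res_*`` is ``(residue_name, residue_number)`` with a 1- or 3-letter
    residue code; contexts are ``""`` (side chain), ``"(O)"`` (backbone
    carbonyl) or ``"(NH)"`` (backbone amide).
    """
    parts = []
    for (resname, resnum), ctx in ((res_a, atom_context_a), (res_b, atom_context_b)):
        if ctx not in _VALID_CTX:
            raise ValueError(f"unknown atom context {ctx!r}")
        code = resname if len(resname) == 1 and resname.isupper() else one_letter(resname)
        if code not in "ACDEFGHIKLMNPQRSTVWY":
            raise ValueError(f"unknown residue code: {resname!r}")
        parts.append(f"{code}{resnum}{ctx}")
    return ":".join(parts)
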