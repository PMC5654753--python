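"""Core structural data model and PDB I/O.

Containers
----------
:class:`AtomRecord`
    One atom: identity (serial, name, element), residue context
    (res_name, res_id, chain_id), Cartesian position in Angstrom, and
    optional per-atom force-field payload (partial charge in units of the
    elementary charge, Lennard-Jones epsilon in kcal/mol and r_min/2 in
    Angstrom) plus an optional moiety tag (``FAD``, ``TRP_C``, ``FE2S2``)
    used to mark pseudo-cofactor groups.
:class:`Structure`
    An ordered list of atoms grouped into chains, with optional unit-cell
    metadata.
:class:`Trajectory`
    A fixed topology (a :class:`Structure`) plus an ordered stack of
    coordinate frames with strictly increasing times in nanoseconds.

Units are Angstrom for lengths, kcal/mol for energies, elementary charges
for partial charges and degrees for angles at the I/O boundary (radians
internally, where noted).

PDB conventions: residue ids are 1-based; the first alternate location is
kept and occupancy is ignored; the moiety tag is carried in the segment
identifier columns (73-76) so it survives a file round-trip.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    PDBFormatError,
    PDBParseError,
    SelectionSyntaxError,
    TopologyMismatchError,
)

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "ChargeSet",
    "CHARGE_ROLES",
    "read_pdb",
    "write_pdb",
    "select",
    "assign_charges",
]

#: Atom roles every charge set must cover: bridging sulfur and iron of the
#: Fe2S2 cluster, and the sulfur, beta carbon and hydrogens of the
#: coordinating cysteines.
CHARGE_ROLES = ("S*", "Fe", "S", "C_B", "H")


@dataclass
class AtomRecord:
    """A single atom record.

    ``position`` is a length-3 float array in Angstrom. ``charge`` is in
    elementary-charge units; ``lj_epsilon`` (kcal/mol) and ``lj_rmin_half``
    (Angstrom) are the Lennard-Jones well depth and half-minimum distance.
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_id: int
    chain_id: str
    position: np.ndarray
    charge: float | None = None
    lj_epsilon: float | None = None
    lj_rmin_half: float | None = None
    moiety_tag: str | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position components must be finite")
        if self.res_id < 1:
            raise ValueError("res_id must be >= 1 (PDB convention)")
        if not self.element:
            raise ValueError("element must be non-empty")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    def copy(self) -> "AtomRecord":
        new = replace(self)
        new.position = self.position.copy()
        return new


class Structure:
    """An ordered collection of atoms grouped into chains.

    Invariants enforced at construction: ``(chain_id, res_id, name)``
    triples are unique, and atoms of one chain are contiguous in the atom
    order.
    """

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        unit_cell: tuple[float, float, float, float, float, float] | None = None,
    ):
        self.atoms: list[AtomRecord] = list(atoms)
        self.unit_cell = unit_cell
        seen: set[tuple[str, int, str]] = set()
        chain_order: list[str] = []
        closed: set[str] = set()
        for atom in self.atoms:
            key = (atom.chain_id, atom.res_id, atom.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key}")
            seen.add(key)
            if not chain_order or chain_order[-1] != atom.chain_id:
                if atom.chain_id in closed:
                    raise ValueError(
                        f"chain {atom.chain_id!r} is not contiguous in atom order"
                    )
                if chain_order:
                    closed.add(chain_order[-1])
                chain_order.append(atom.chain_id)
        self._chain_order = chain_order

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        return list(self._chain_order)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in Angstrom (a fresh copy)."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, xyz in zip(self.atoms, coords):
            atom.position = xyz.copy()

    def chain_atom_indices(self, chain_id: str) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.chain_id == chain_id], dtype=int
        )

    def subset(self, indices: Iterable[int]) -> "Structure":
        """New structure holding copies of the indexed atoms, in order."""
        return Structure([self.atoms[i].copy() for i in indices])

    def copy(self) -> "Structure":
        return Structure([a.copy() for a in self.atoms], unit_cell=self.unit_cell)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Structure {len(self.atoms)} atoms, {len(self.chains)} chains>"


class Trajectory:
    """Fixed topology plus ordered coordinate frames.

    ``frames`` is a (n_frames, n_atoms, 3) array in Angstrom and
    ``frame_times`` strictly increasing times in nanoseconds.
    """

    def __init__(
        self,
        topology: Structure,
        frames: np.ndarray,
        frame_times: Sequence[float] | None = None,
    ):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[1:] != (len(topology), 3):
            raise ValueError(
                "frames must have shape (n_frames, n_atoms, 3) matching topology"
            )
        if frame_times is None:
            frame_times = np.arange(frames.shape[0], dtype=float)
        frame_times = np.asarray(frame_times, dtype=float)
        if frame_times.shape != (frames.shape[0],):
            raise ValueError("one time per frame required")
        if frames.shape[0] > 1 and not np.all(np.diff(frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        self.topology = topology
        self.frames = frames
        self.frame_times = frame_times

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def frame_structure(self, index: int) -> Structure:
        s = self.topology.copy()
        s.set_coords(self.frames[index])
        return s

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<Trajectory {self.n_frames} frames x {len(self.topology)} atoms, "
            f"t = {self.frame_times[0]:g}..{self.frame_times[-1]:g} ns>"
        )


@dataclass(frozen=True)
class ChargeSet:
    """Named set of partial charges for the Fe2S2/cysteine moiety roles."""

    name: str
    charges: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [r for r in CHARGE_ROLES if r not in self.charges]
        if missing:
            raise ConfigurationError(
                f"charge set {self.name!r} is missing roles: {missing}"
            )

    def __getitem__(self, role: str) -> float:
        try:
            return float(self.charges[role])
        except KeyError:
            raise ConfigurationError(
                f"role {role!r} not present in charge set {self.name!r}"
            ) from None


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

_TIMES_REMARK = "REMARK   3 FRAME_TIMES_NS"

# The segid column is 4 characters wide; longer moiety tags use fixed
# short codes so they survive a file round-trip.
_TAG_TO_SEGID = {"FE2S2": "FES2", "TRP_C": "TRPC"}
_SEGID_TO_TAG = {v: k for k, v in _TAG_TO_SEGID.items()}


def _parse_atom_line(line: str, line_number: int) -> AtomRecord:
    # Columns follow the PDB v3 fixed-column layout.
    if len(line) < 54:
        raise PDBParseError(line_number, "ATOM record shorter than coordinate fields")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        res_id = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(line_number, f"malformed ATOM record ({exc})") from None
    segid = line[72:76].strip() if len(line) >= 76 else ""
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # Fall back on the leading letter of the atom name.
        stripped = name.lstrip("0123456789")
        element = stripped[:1].upper() if stripped else "X"
    if not name:
        raise PDBParseError(line_number, "empty atom name")
    if res_id < 1:
        raise PDBParseError(line_number, f"res_id {res_id} violates 1-based convention")
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        res_name=res_name,
        res_id=res_id,
        chain_id=chain_id,
        position=np.array([x, y, z]),
        moiety_tag=_SEGID_TO_TAG.get(segid, segid) or None,
    )


def read_pdb(path: str | Path) -> Structure | Trajectory:
    """Read a PDB file into a :class:`Structure` or :class:`Trajectory`.

    Multi-model files (MODEL/ENDMDL blocks) yield a trajectory whose
    topology is taken from the first model; all models must contain the
    identical atom set in the same order. Frame times are recovered from a
    ``REMARK   3 FRAME_TIMES_NS`` header when present (written by
    :func:`write_pdb`) and default to 1-ns spacing otherwise.
    """
    path = Path(path)
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False
    saw_model_records = False
    unit_cell = None
    frame_times: list[float] = []
    seen_altloc: set[tuple[str, int, str]] = set()

    with open(path) as handle:
        for line_number, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            record = line[:6].strip()
            if line.startswith(_TIMES_REMARK):
                frame_times.extend(float(tok) for tok in line.split()[3:])
            elif record == "CRYST1":
                try:
                    unit_cell = tuple(
                        float(line[i : i + 9]) if k < 3 else float(line[i : i + 7])
                        for k, i in enumerate((6, 15, 24, 33, 40, 47))
                    )
                except ValueError:
                    raise PDBParseError(line_number, "malformed CRYST1 record")
            elif record == "MODEL":
                saw_model_records = True
                in_model = True
                current = []
                seen_altloc = set()
            elif record == "ENDMDL":
                in_model = False
                models.append(current)
                current = []
            elif record in ("ATOM", "HETATM"):
                altloc = line[16] if len(line) > 16 else " "
                atom = _parse_atom_line(line, line_number)
                key = (atom.chain_id, atom.res_id, atom.name)
                if altloc not in (" ", ""):
                    if key in seen_altloc:
                        continue  # keep first altloc only
                seen_altloc.add(key)
                current.append(atom)

    if current and (not saw_model_records or in_model):
        models.append(current)
    if not models or not models[0]:
        raise PDBParseError(0, f"no ATOM records found in {path}")

    first = models[0]
    if len(models) == 1 and not saw_model_records:
        return Structure(first, unit_cell=unit_cell)

    identities = [(a.chain_id, a.res_id, a.name, a.res_name) for a in first]
    frames = np.empty((len(models), len(first), 3))
    for m, model in enumerate(models):
        if [(a.chain_id, a.res_id, a.name, a.res_name) for a in model] != identities:
            raise TopologyMismatchError(
                f"model {m + 1} atom set differs from model 1 in {path}"
            )
        frames[m] = [a.position for a in model]
    topology = Structure(first, unit_cell=unit_cell)
    times = frame_times if len(frame_times) == len(models) else None
    return Trajectory(topology, frames, frame_times=times)


def _format_atom_name(name: str) -> str:
    # Standard PDB alignment: up-to-3-character names start in column 14.
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3}"


def _atom_line(atom: AtomRecord, serial: int) -> str:
    x, y, z = atom.position
    for value in (x, y, z):
        if not abs(value) < 10000.0 - 0.0005:
            raise PDBFormatError(
                f"coordinate {value:.3f} outside PDB fixed-column range"
            )
    if len(atom.chain_id) != 1:
        raise PDBFormatError(
            f"chain id {atom.chain_id!r} is not a single character; "
            "PDB output requires 1-character chain identifiers"
        )
    tag = atom.moiety_tag or ""
    segid = _TAG_TO_SEGID.get(tag, tag)
    if len(segid) > 4:
        raise PDBFormatError(
            f"moiety tag {tag!r} does not fit the 4-character segid column; "
            "register a short code for it"
        )
    return (
        f"ATOM  {serial:>5d} {_format_atom_name(atom.name)} "
        f"{atom.res_name:>3} {atom.chain_id}{atom.res_id:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}      "
        f"{segid:<4}{atom.element[:2]:>2}"
    )


def _structure_lines(structure: Structure) -> list[str]:
    lines = []
    serial = 0
    prev_chain: str | None = None
    for atom in structure.atoms:
        if prev_chain is not None and atom.chain_id != prev_chain:
            lines.append("TER")
        serial += 1
        lines.append(_atom_line(atom, serial % 100000))
        prev_chain = atom.chain_id
    return lines


def write_pdb(obj: Structure | Trajectory, path: str | Path) -> None:
    """Write a structure or trajectory in fixed-column PDB format.

    Trajectories are written as MODEL/ENDMDL blocks with frame times
    recorded in a REMARK header so that a read/write cycle preserves them.
    """
    path = Path(path)
    lines: list[str] = []
    if isinstance(obj, Trajectory):
        times = " ".join(f"{t:g}" for t in obj.frame_times)
        lines.append(f"{_TIMES_REMARK} {times}")
        if obj.topology.unit_cell is not None:
            lines.append(_cryst1_line(obj.topology.unit_cell))
        for m in range(obj.n_frames):
            lines.append(f"MODEL     {m + 1:>4d}")
            lines.extend(_structure_lines(obj.frame_structure(m)))
            lines.append("ENDMDL")
    else:
        if obj.unit_cell is not None:
            lines.append(_cryst1_line(obj.unit_cell))
        lines.extend(_structure_lines(obj))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _cryst1_line(cell: tuple[float, float, float, float, float, float]) -> str:
    a, b, c, alpha, beta, gamma = cell
    return (
        f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}"
        f"{alpha:7.2f}{beta:7.2f}{gamma:7.2f} P 1           1"
    )


# ---------------------------------------------------------------------------
# Selection mini-grammar
# ---------------------------------------------------------------------------
#
#   expr     := or_expr
#   or_expr  := and_expr ("or" and_expr)*
#   and_expr := unary ("and" unary)*
#   unary    := "not" unary | "(" expr ")" | predicate
#   predicate:= "chain" ID+ | "resid" (INT | INT-INT | INT:INT)+
#             | "resname" NAME+ | "name" NAME+ | "moiety" TAG+
#             | "heavy" | "all"

_KEYWORDS = {"chain", "resid", "resname", "name", "moiety", "heavy", "all",
             "and", "or", "not", "(", ")"}

_RANGE_RE = re.compile(r"^(-?\d+)[-:](-?\d+)$")


def _tokenize(expression: str) -> list[str]:
    return expression.replace("(", " ( ").replace(")", " ) ").split()


class _Parser:
    def __init__(self, tokens: list[str], expression: str):
        self.tokens = tokens
        self.pos = 0
        self.expression = expression

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError(
                f"unexpected end of expression in {self.expression!r}"
            )
        self.pos += 1
        return tok

    def parse(self):
        node = self.parse_or()
        if self.peek() is not None:
            raise SelectionSyntaxError(
                f"trailing token {self.peek()!r} in {self.expression!r}"
            )
        return node

    def parse_or(self):
        node = self.parse_and()
        while self.peek() == "or":
            self.take()
            rhs = self.parse_and()
            node = ("or", node, rhs)
        return node

    def parse_and(self):
        node = self.parse_unary()
        while self.peek() == "and":
            self.take()
            rhs = self.parse_unary()
            node = ("and", node, rhs)
        return node

    def parse_unary(self):
        tok = self.peek()
        if tok == "not":
            self.take()
            return ("not", self.parse_unary())
        if tok == "(":
            self.take()
            node = self.parse_or()
            if self.take() != ")":
                raise SelectionSyntaxError(f"unbalanced parentheses in {self.expression!r}")
            return node
        return self.parse_predicate()

    def parse_predicate(self):
        keyword = self.take()
        if keyword == "heavy":
            return ("heavy",)
        if keyword == "all":
            return ("all",)
        if keyword not in ("chain", "resid", "resname", "name", "moiety"):
            raise SelectionSyntaxError(
                f"unknown selection keyword {keyword!r} in {self.expression!r}"
            )
        values: list[str] = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            values.append(self.take())
        if not values:
            raise SelectionSyntaxError(
                f"keyword {keyword!r} requires at least one value"
            )
        if keyword == "resid":
            ids: set[int] = set()
            for value in values:
                match = _RANGE_RE.match(value)
                if match:
                    lo, hi = int(match.group(1)), int(match.group(2))
                    ids.update(range(min(lo, hi), max(lo, hi) + 1))
                else:
                    try:
                        ids.add(int(value))
                    except ValueError:
                        raise SelectionSyntaxError(
                            f"resid value {value!r} is not an integer or range"
                        ) from None
            return ("resid", frozenset(ids))
        return (keyword, frozenset(values))


def _evaluate(node, atom: AtomRecord) -> bool:
    op = node[0]
    if op == "and":
        return _evaluate(node[1], atom) and _evaluate(node[2], atom)
    if op == "or":
        return _evaluate(node[1], atom) or _evaluate(node[2], atom)
    if op == "not":
        return not _evaluate(node[1], atom)
    if op == "heavy":
        return atom.is_heavy
    if op == "all":
        return True
    if op == "chain":
        return atom.chain_id in node[1]
    if op == "resid":
        return atom.res_id in node[1]
    if op == "resname":
        return atom.res_name in node[1]
    if op == "name":
        return atom.name in node[1]
    if op == "moiety":
        return atom.moiety_tag in node[1]
    raise AssertionError(f"unhandled node {node!r}")


def select(structure: Structure, expression: str) -> np.ndarray:
    """Evaluate a selection expression, returning atom indices in order.

    The grammar supports conjunction/disjunction/negation of the
    predicates ``chain``, ``resid`` (integers or ``lo-hi`` ranges),
    ``resname``, ``name``, ``moiety`` and ``heavy``. The result is a
    deterministic, ascending index array; empty selections are valid.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionSyntaxError("empty selection expression")
    tree = _Parser(tokens, expression).parse()
    return np.array(
        [i for i, atom in enumerate(structure.atoms) if _evaluate(tree, atom)],
        dtype=int,
    )


# ---------------------------------------------------------------------------
# Charge assignment
# ---------------------------------------------------------------------------

def assign_charges(
    structure: Structure,
    charge_set: ChargeSet,
    role_map: Mapping[int, str],
) -> Structure:
    """Return a copy with charges from ``charge_set`` applied via ``role_map``.

    ``role_map`` maps atom indices to charge-set roles (``S*``, ``Fe``,
    ``S``, ``C_B``, ``H``). Mapped atoms get the role's charge; everything
    else — coordinates included — is untouched.
    """
    out = structure.copy()
    for index, role in role_map.items():
        if not 0 <= index < len(out.atoms):
            raise ConfigurationError(f"role map index {index} out of range")
        out.atoms[index].charge = charge_set[role]
    return out
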