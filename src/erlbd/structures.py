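"""Structure and sequence containers with PDB/FASTA input-output.

The pipeline works on a deliberately small in-memory model: an ordered
list of :class:`Atom` records grouped lazily into residues.  Parsing
policy (documented, deterministic):

* only the first MODEL of a multi-model file is read;
* for alternate locations of the same atom, the conformer with the
  highest occupancy is kept, ties going to the first listed;
* waters (HOH/WAT/DOD) are dropped unless ``keep_waters=True``;
* residue numbering and insertion codes are taken verbatim from the
  source file — pairing across structures is done by sequence alignment,
  never by numbering.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_3to1

from .errors import (
    EmptySelectionError,
    EmptyStructureError,
    ParseError,
    ValidationError,
)

WATER_NAMES = {"HOH", "WAT", "DOD"}

#: One-letter amino-acid alphabet accepted in :class:`SequenceRecord`.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"

_3TO1 = {k.upper(): v for k, v in protein_letters_3to1.items()}

#: Atom-name sets for the selection specs understood by
#: :func:`extract_coordinates` and the superposition pipeline.
SELECTIONS = ("CA", "backbone", "all-heavy")
_BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class Atom:
    """A single atom record.

    ``residue_number`` is the author numbering as printed in the source
    file (1-based by convention); ``icode`` carries the insertion code.
    ``position`` is in Angstroms.
    """

    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    is_hetero: bool = False
    icode: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValidationError(
                f"atom {self.name}: position must have 3 finite components"
            )
        object.__setattr__(self, "position", pos)
        if not self.element:
            raise ValidationError(f"atom {self.name}: element must be non-empty")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.icode)

    @property
    def label(self) -> "AtomLabel":
        return AtomLabel(
            self.chain_id, self.residue_number, self.residue_name, self.name
        )


class AtomLabel(NamedTuple):
    chain_id: str
    residue_number: int
    residue_name: str
    name: str

    def __str__(self) -> str:  # e.g. "A/GLU42/OE1"
        return f"{self.chain_id}/{self.residue_name}{self.residue_number}/{self.name}"


class ResidueLabel(NamedTuple):
    chain_id: str
    residue_number: int
    icode: str
    residue_name: str

    def __str__(self) -> str:
        return f"{self.chain_id}/{self.residue_name}{self.residue_number}{self.icode}"


@dataclass
class Residue:
    label: ResidueLabel
    atoms: list[Atom]

    @property
    def one_letter(self) -> str:
        return _3TO1.get(self.label.residue_name.upper(), "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element.upper() != "H"]


@dataclass
class Structure:
    """An ordered set of atoms; residue iteration preserves file order."""

    atoms: list[Atom] = field(default_factory=list)
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.atoms)

    def residues(self, hetero: bool | None = None) -> list[Residue]:
        """Group atoms into residues in order of first appearance.

        ``hetero=False`` keeps polymer residues only, ``True`` hetero
        only, ``None`` everything.
        """
        out: list[Residue] = []
        index: dict[tuple, int] = {}
        for a in self.atoms:
            if hetero is not None and a.is_hetero != hetero:
                continue
            key = a.residue_key
            if key not in index:
                index[key] = len(out)
                out.append(
                    Residue(
                        ResidueLabel(a.chain_id, a.residue_number, a.icode, a.residue_name),
                        [],
                    )
                )
            out[index[key]].atoms.append(a)
        return out

    def polymer_residues(self) -> list[Residue]:
        return self.residues(hetero=False)

    def sequence(self) -> str:
        """One-letter sequence of the polymer residues, X for non-standard."""
        return "".join(r.one_letter for r in self.polymer_residues())

    def hetero_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_hetero]

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element.upper() != "H"]

    def coordinates(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.position for a in self.atoms])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with every position mapped to R x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        atoms = [replace(a, position=R @ a.position + t) for a in self.atoms]
        return Structure(atoms, label=self.label, metadata=dict(self.metadata))


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence over the 20 one-letter codes plus X."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        seq = self.residues.upper()
        if not seq:
            raise ValidationError(f"sequence record {self.id!r} is empty")
        bad = set(seq) - set(AA_ALPHABET)
        if bad:
            raise ValidationError(
                f"sequence record {self.id!r} contains invalid residues: "
                f"{''.join(sorted(bad))}"
            )
        object.__setattr__(self, "residues", seq)

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# PDB parsing / writing


def _guess_element(name_field: str) -> str:
    """Element from the 4-character atom-name field when column 77-78 is blank."""
    stripped = "".join(c for c in name_field if c.isalpha())
    if not stripped:
        return ""
    # a name starting in column 13 (no leading space) with 2+ letters is a
    # two-letter element (FE, ZN, ...) unless it is a hydrogen variant
    if len(name_field) >= 1 and name_field[0] != " " and len(stripped) >= 2:
        two = stripped[:2].upper()
        if two[0] != "H":
            return two.capitalize()
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, str]:
    line = line.rstrip("\n").ljust(80)
    record = line[:6]
    name = line[12:16].strip()
    altloc = line[16].strip()
    resname = line[17:20].strip()
    chain = line[21].strip() or " "
    icode = line[26].strip()
    try:
        resnum = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed coordinate field: {exc}") from exc
    try:
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
    except ValueError:
        occ = 1.0
    try:
        bfac = float(line[60:66]) if line[60:66].strip() else 0.0
    except ValueError:
        bfac = 0.0
    element = line[76:78].strip().capitalize() or _guess_element(line[12:16])
    atom = Atom(
        name=name,
        element=element,
        residue_name=resname,
        residue_number=resnum,
        chain_id=chain,
        position=np.array([x, y, z]),
        is_hetero=record.startswith("HETATM"),
        icode=icode,
        occupancy=occ,
        bfactor=bfac,
    )
    # altloc is carried out-of-band: Atom is frozen and altloc only matters
    # during conformer resolution
    return atom, altloc


def parse_pdb(text: str, label: str = "", keep_waters: bool = False) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Reads ATOM/HETATM records of the first model only.  See the module
    docstring for the altloc and water policy.
    """
    raw: list[tuple[Atom, str]] = []
    model_count = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            model_count += 1
            if model_count > 1:
                break
        elif rec == "ENDMDL":
            if raw:
                break
        elif rec in ("ATOM", "HETATM"):
            atom, altloc = _parse_atom_line(line, lineno)
            if not keep_waters and atom.residue_name in WATER_NAMES:
                continue
            raw.append((atom, altloc))
    if not raw:
        raise EmptyStructureError(f"{label or 'source'}: no atom records found")

    # altloc resolution: per (residue, atom name), keep the conformer with
    # the highest occupancy; first listed wins ties
    best: dict[tuple, tuple[float, int, Atom]] = {}
    order: list[tuple] = []
    for i, (atom, altloc) in enumerate(raw):
        key = (*atom.residue_key, atom.name)
        if key not in best:
            best[key] = (atom.occupancy, i, atom)
            order.append(key)
        elif altloc and atom.occupancy > best[key][0]:
            best[key] = (atom.occupancy, best[key][1], atom)
    atoms = sorted((best[k] for k in order), key=lambda t: t[1])
    return Structure([a for _, _, a in atoms], label=label)


def read_pdb(source, label: str = "", keep_waters: bool = False) -> Structure:
    """Read a PDB file from a path or an open text/byte stream."""
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, bytes):
            data = data.decode("ascii", errors="replace")
        return parse_pdb(data, label=label, keep_waters=keep_waters)
    path = os.fspath(source)
    with open(path) as fh:
        return parse_pdb(
            fh.read(), label=label or os.path.basename(path), keep_waters=keep_waters
        )


def format_pdb(structure: Structure) -> str:
    """Render a structure as fixed-column PDB text (one model, TER, END)."""
    lines = []
    for serial, a in enumerate(structure.atoms, start=1):
        record = "HETATM" if a.is_hetero else "ATOM  "
        name = a.name
        if len(name) < 4:
            name = name.ljust(3) if len(a.element) == 2 else (" " + name).ljust(4)
        name = name[:4].ljust(4)
        lines.append(
            f"{record}{serial:5d} {name}{'':1s}{a.residue_name:>3s} "
            f"{a.chain_id:1s}{a.residue_number:4d}{a.icode or ' ':1s}   "
            f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
            f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element.upper():>2s}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb(structure: Structure, target) -> None:
    text = format_pdb(structure)
    if hasattr(target, "write"):
        target.write(text)
    else:
        with open(os.fspath(target), "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(source) -> list[SequenceRecord]:
    """Read FASTA records; ids are the header up to the first whitespace."""
    if hasattr(source, "read"):
        handle = source
    else:
        handle = open(os.fspath(source))
    try:
        records = [
            SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")
        ]
    finally:
        if handle is not source:
            handle.close()
    if not records:
        raise ValidationError("no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], target, width: int = 60) -> None:
    lines = []
    for rec in records:
        lines.append(f">{rec.id}")
        for i in range(0, len(rec.residues), width):
            lines.append(rec.residues[i : i + width])
    text = "\n".join(lines) + "\n"
    if hasattr(target, "write"):
        target.write(text)
    else:
        with open(os.fspath(target), "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# Coordinate extraction


def _selected_names(selection: str) -> tuple[str, ...] | None:
    sel = selection.replace("-only", "").strip()
    low = sel.lower()
    if low == "ca":
        return ("CA",)
    if low == "backbone":
        return _BACKBONE_NAMES
    if low in ("all-heavy", "heavy", "all_heavy"):
        return None  # any heavy atom
    raise ValidationError(
        f"unknown selection {selection!r}; expected one of {SELECTIONS}"
    )


def extract_coordinates(
    structure: Structure, selection: str = "CA"
) -> tuple[list[AtomLabel], np.ndarray]:
    """Coordinates of the selected polymer atoms, in structure order.

    ``selection`` is ``"CA"``, ``"backbone"`` or ``"all-heavy"``.  Returns
    ``(labels, coords)`` with one ``(chain, residue_number, residue_name,
    atom name)`` label per coordinate row, for later pairing.
    """
    names = _selected_names(selection)
    labels: list[AtomLabel] = []
    coords: list[np.ndarray] = []
    for a in structure.atoms:
        if a.is_hetero:
            continue
        if names is None:
            if a.element.upper() == "H":
                continue
        elif a.name not in names:
            continue
        labels.append(a.label)
        coords.append(a.position)
    if not coords:
        raise EmptySelectionError(
            f"selection {selection!r} matched no atoms in {structure.label or 'structure'}"
        )
    return labels, np.stack(coords)
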