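"""Reading, validating and normalizing chemical-shift and intensity tables.

Two input dialects are supported for per-residue backbone chemical shifts:

* a simple TSV dialect with header ``residue_index  residue_type  atom  shift``
  (tab-separated, ``#`` comments), and
* a read-only subset of NMR-STAR 3.x restricted to the ``Atom_chem_shift``
  loop (the deposit format used by the BMRB), identified by its
  ``_Atom_chem_shift.*`` tags. All other save frames are ignored.

Residue numbering is 1-based and taken verbatim from the file's sequence
codes; three-letter residue names are mapped to one-letter codes and the
carbonyl atom name ``C`` is normalized to ``CO``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, TextIO

__all__ = [
    "ATOMS",
    "ProteinSequence",
    "ShiftRecord",
    "ShiftTable",
    "IntensityTable",
    "ShiftParseError",
    "ShiftValidationError",
    "parse_shift_table",
    "attach_sequence",
    "write_shift_tsv",
]

#: Backbone atoms carried by a shift table. ``CO`` is the carbonyl carbon
#: (source files may spell it ``C``); ``N`` and ``H`` are the amide pair.
ATOMS = ("CA", "CB", "CO", "N", "H")

_ATOM_ALIASES = {"C": "CO", "HN": "H"}

AA1 = "ACDEFGHIKLMNPQRSTVWY"

AA3TO1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}

INTENSITY_STATUSES = ("assigned", "proline", "unassigned", "overlapped")


class ShiftParseError(ValueError):
    """Malformed input that cannot be read at all (names the offending line)."""


class ShiftValidationError(ValueError):
    """Readable input that violates a table invariant."""


@dataclass(frozen=True)
class ProteinSequence:
    """One-letter amino-acid sequence with an author-defined first index."""

    residues: str
    first_index: int = 1

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ShiftValidationError("sequence must contain at least one residue")
        bad = set(self.residues) - set(AA1)
        if bad:
            raise ShiftValidationError(f"non-canonical residue letters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def last_index(self) -> int:
        return self.first_index + len(self.residues) - 1

    def residue_type(self, index: int) -> str:
        if not (self.first_index <= index <= self.last_index):
            raise ShiftValidationError(
                f"residue index {index} outside sequence range "
                f"[{self.first_index}, {self.last_index}]"
            )
        return self.residues[index - self.first_index]


@dataclass(frozen=True)
class ShiftRecord:
    """A single observed chemical shift for one backbone atom of one residue."""

    residue_index: int
    residue_type: str
    atom: str
    shift: float

    def __post_init__(self) -> None:
        if self.atom not in ATOMS:
            raise ShiftValidationError(f"unknown atom {self.atom!r}; expected one of {ATOMS}")
        if self.residue_type not in AA1:
            raise ShiftValidationError(f"unknown residue type {self.residue_type!r}")
        if not (self.shift == self.shift and abs(self.shift) != float("inf")):
            raise ShiftValidationError(
                f"non-finite shift for residue {self.residue_index} atom {self.atom}"
            )


@dataclass
class ShiftTable:
    """Per-residue, per-atom chemical shifts, optionally tied to a sequence."""

    records: list[ShiftRecord]
    sequence: ProteinSequence | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        for rec in self.records:
            key = (rec.residue_index, rec.atom)
            if key in seen:
                raise ShiftValidationError(f"duplicate shift record for {key}")
            seen.add(key)

    def shift(self, residue_index: int, atom: str) -> float | None:
        for rec in self.records:
            if rec.residue_index == residue_index and rec.atom == atom:
                return rec.shift
        return None

    def residue_indices(self) -> list[int]:
        return sorted({rec.residue_index for rec in self.records})


@dataclass
class IntensityTable:
    """Per-residue peak intensities across an ordered list of conditions.

    ``status`` marks why a residue is or is not evaluable: prolines have no
    amide proton, and unassigned or overlapped signals cannot be integrated.
    """

    condition_labels: list[str]
    values: dict[int, list[float]]
    status: dict[int, str] = field(default_factory=dict)
    sequence: ProteinSequence | None = None

    def __post_init__(self) -> None:
        n = len(self.condition_labels)
        for idx, vals in self.values.items():
            if len(vals) != n:
                raise ShiftValidationError(
                    f"residue {idx}: {len(vals)} intensities for {n} conditions"
                )
            for v in vals:
                if v == v and v < 0:  # NaN marks missing
                    raise ShiftValidationError(f"negative intensity at residue {idx}")
        for idx in self.values:
            self.status.setdefault(idx, "assigned")
        for idx, st in self.status.items():
            if st not in INTENSITY_STATUSES:
                raise ShiftValidationError(f"unknown status {st!r} at residue {idx}")

    def residue_indices(self) -> list[int]:
        return sorted(self.values)


def _as_stream(source: str | TextIO) -> TextIO:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def _map_residue_name(name: str, lineno: int) -> str:
    name = name.upper()
    if len(name) == 1 and name in AA1:
        return name
    if name in AA3TO1:
        return AA3TO1[name]
    raise ShiftValidationError(f"line {lineno}: unknown residue name {name!r}")


def _map_atom(name: str, lineno: int) -> str:
    name = name.upper()
    name = _ATOM_ALIASES.get(name, name)
    if name not in ATOMS:
        raise ShiftValidationError(f"line {lineno}: unsupported atom name {name!r}")
    return name


def parse_shift_table(source: str | TextIO, dialect: str = "tsv") -> ShiftTable:
    """Parse a chemical-shift table from ``tsv`` or ``nmrstar`` input.

    Duplicate (residue, atom) rows are rejected; unknown residue or atom
    names raise :class:`ShiftValidationError` naming the line.
    """
    stream = _as_stream(source)
    if dialect == "tsv":
        records = _parse_tsv(stream)
    elif dialect == "nmrstar":
        records = _parse_nmrstar(stream)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    records.sort(key=lambda r: (r.residue_index, ATOMS.index(r.atom)))
    return ShiftTable(records=records, provenance=f"parsed ({dialect})")


def _parse_tsv(stream: TextIO) -> list[ShiftRecord]:
    records: list[ShiftRecord] = []
    header_seen = False
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if not header_seen and fields[0].lower() in ("residue_index", "residue"):
            header_seen = True
            continue
        if len(fields) < 4:
            raise ShiftParseError(f"line {lineno}: expected 4 columns, got {len(fields)}")
        try:
            idx = int(fields[0])
            shift = float(fields[3])
        except ValueError as exc:
            raise ShiftParseError(f"line {lineno}: {exc}") from None
        records.append(
            ShiftRecord(
                residue_index=idx,
                residue_type=_map_residue_name(fields[1], lineno),
                atom=_map_atom(fields[2], lineno),
                shift=shift,
            )
        )
    return records


# NMR-STAR tag names accepted for each required Atom_chem_shift column.
_STAR_COLS = {
    "seq": ("seq_id", "comp_index_id"),
    "comp": ("comp_id",),
    "atom": ("atom_id",),
    "val": ("val",),
}


def _parse_nmrstar(stream: TextIO) -> list[ShiftRecord]:
    """Consume the first ``Atom_chem_shift`` loop of an NMR-STAR 3.x file.

    Only the sequence-code, residue-name, atom-name and value columns are
    read; ambiguity codes and shift errors are ignored.
    """
    lines = stream.read().splitlines()
    i = 0
    n = len(lines)
    while i < n:
        if lines[i].strip().lower() == "loop_":
            tags: list[str] = []
            j = i + 1
            while j < n and lines[j].strip().startswith("_"):
                tags.append(lines[j].strip())
                j += 1
            if any(t.lower().startswith("_atom_chem_shift.") for t in tags):
                return _parse_star_loop_body(tags, lines, j)
        i += 1
    raise ShiftParseError("no Atom_chem_shift loop found in NMR-STAR input")


def _parse_star_loop_body(tags: list[str], lines: list[str], start: int) -> list[ShiftRecord]:
    short = [t.split(".", 1)[1].lower() if "." in t else t.lower() for t in tags]
    col: dict[str, int] = {}
    for key, names in _STAR_COLS.items():
        for name in names:
            if name in short:
                col[key] = short.index(name)
                break
        else:
            raise ShiftParseError(
                f"Atom_chem_shift loop lacks a recognizable {key!r} column"
            )
    records: list[ShiftRecord] = []
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        token = raw.strip()
        if token.lower() in ("stop_",) or token.lower().startswith("save_"):
            break
        if not token or token.startswith("#"):
            continue
        fields = token.split()
        if len(fields) <= max(col.values()):
            raise ShiftParseError(
                f"line {lineno}: loop row has {len(fields)} fields, "
                f"expected at least {max(col.values()) + 1}"
            )
        try:
            idx = int(fields[col["seq"]])
            val = float(fields[col["val"]])
        except ValueError as exc:
            raise ShiftParseError(f"line {lineno}: {exc}") from None
        atom_raw = fields[col["atom"]].upper()
        if _ATOM_ALIASES.get(atom_raw, atom_raw) not in ATOMS:
            continue  # side-chain shifts etc. are not consumed
        records.append(
            ShiftRecord(
                residue_index=idx,
                residue_type=_map_residue_name(fields[col["comp"]], lineno),
                atom=_map_atom(atom_raw, lineno),
                shift=val,
            )
        )
    return records


def write_shift_tsv(table: ShiftTable, stream: TextIO | None = None) -> str:
    """Serialize a shift table to the TSV dialect. Round-trips bit-exactly."""
    out = io.StringIO()
    out.write("residue_index\tresidue_type\tatom\tshift\n")
    for rec in sorted(table.records, key=lambda r: (r.residue_index, ATOMS.index(r.atom))):
        out.write(f"{rec.residue_index}\t{rec.residue_type}\t{rec.atom}\t{rec.shift!r}\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def attach_sequence(
    table: ShiftTable | IntensityTable, seq: ProteinSequence
) -> ShiftTable | IntensityTable:
    """Cross-check a table against a sequence and return a sequence-bound copy.

    For shift tables every record's residue type must match the sequence
    letter at its index. For intensity tables, proline positions are forced
    to ``status='proline'``.
    """
    if isinstance(table, ShiftTable):
        for rec in table.records:
            expected = seq.residue_type(rec.residue_index)
            if rec.residue_type != expected:
                raise ShiftValidationError(
                    f"residue type mismatch at {rec.residue_index}: "
                    f"table has {rec.residue_type!r}, sequence has {expected!r}"
                )
        return ShiftTable(
            records=list(table.records), sequence=seq, provenance=table.provenance
        )
    if isinstance(table, IntensityTable):
        status = dict(table.status)
        for idx in table.values:
            if seq.residue_type(idx) == "P":
                status[idx] = "proline"
        return IntensityTable(
            condition_labels=list(table.condition_labels),
            values={k: list(v) for k, v in table.values.items()},
            status=status,
            sequence=seq,
        )
    raise TypeError(f"cannot attach a sequence to {type(table).__name__}")
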