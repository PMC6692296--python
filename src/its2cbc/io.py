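"""Readers and writers for the sequence/structure formats the pipeline touches.

Supported formats: plain and aligned FASTA, the Mfold/RNAstructure CT
dialect, and Vienna dot-bracket. Everything is normalized on load into the
domain model: sequences are uppercase RNA (T→U), coordinates are 1-based
inclusive, and structures are validated to be nested (pseudoknot-free) with
no base triples — the downstream column mapping relies on both.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "StructureError",
    "SequenceRecord",
    "Region",
    "AnnotatedStructure",
    "read_fasta",
    "read_alignment",
    "read_ct",
    "read_vienna",
    "write_vienna",
]

#: Residue alphabet accepted after normalization. IUPAC ambiguity codes other
#: than N are rejected: the 1–8 pair code is undefined for them, whereas N is
#: well-defined as "never pairing-capable".
ALPHABET = frozenset("ACGUN")
GAP = "-"


class StructureError(ValueError):
    """Raised on malformed or inconsistent sequence/structure input."""


def _normalize(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _validate_residues(seq: str, *, label: str, allow_gap: bool = False) -> None:
    allowed = ALPHABET | {GAP} if allow_gap else ALPHABET
    for pos, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise StructureError(
                f"{label}: character {ch!r} at position {pos} is outside the "
                f"accepted alphabet {{A,C,G,U,N}}"
                + (" plus gap '-'" if allow_gap else "")
            )


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence (a strain or accession).

    ``seq`` is uppercase, U-normalized RNA; for alignment rows it may
    additionally contain ``-`` gaps.
    """

    id: str
    seq: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise StructureError("sequence record requires a non-empty id")
        if not self.seq:
            raise StructureError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.seq)

    def base(self, i: int) -> str:
        """Residue at 1-based position ``i``."""
        return self.seq[i - 1]


@dataclass(frozen=True)
class Region:
    """A named 1-based inclusive interval on a sequence."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise StructureError(
                f"region {self.name!r}: invalid interval ({self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def _check_nested(pairs: Sequence[tuple[int, int]]) -> None:
    ordered = sorted(pairs)
    for idx, (i, j) in enumerate(ordered):
        for k, l in ordered[idx + 1 :]:
            if k >= j:
                break
            if i < k <= j < l:  # crossing: i < k < j < l
                raise StructureError(
                    f"pseudoknot: pairs ({i},{j}) and ({k},{l}) cross"
                )


@dataclass(frozen=True)
class AnnotatedStructure:
    """A sequence plus its base-pairing map and named region annotations.

    Pairs are stored 1-based with 5′ index first (i < j). Validity is
    enforced at construction: indices in range, no base triples, no
    pseudoknots, regions within the sequence.
    """

    record: SequenceRecord
    pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    regions: tuple[Region, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.record)
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= n):
                raise StructureError(
                    f"{self.record.id}: pair ({i},{j}) out of range for length {n}"
                )
            for x in (i, j):
                if x in seen:
                    raise StructureError(
                        f"{self.record.id}: position {x} participates in more "
                        "than one base pair"
                    )
                seen.add(x)
        _check_nested(sorted(self.pairs))
        for r in self.regions:
            if r.end > n:
                raise StructureError(
                    f"{self.record.id}: region {r.name!r} ends at {r.end}, "
                    f"beyond sequence length {n}"
                )

    @property
    def id(self) -> str:
        return self.record.id

    @property
    def seq(self) -> str:
        return self.record.seq

    def __len__(self) -> int:
        return len(self.record)

    def partner_map(self) -> dict[int, int]:
        """Map each paired position to its partner (both directions)."""
        m: dict[int, int] = {}
        for i, j in self.pairs:
            m[i] = j
            m[j] = i
        return m

    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(f"{self.record.id}: no region named {name!r}")


# ---------------------------------------------------------------------------
# FASTA


def _read_fasta_records(
    path: str | Path, *, allow_gap: bool
) -> list[SequenceRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalize(str(rec.seq))
        _validate_residues(seq, label=f"{path.name}:{rec.id}", allow_gap=allow_gap)
        if rec.id in seen:
            raise StructureError(f"{path.name}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=seq, source=str(path)))
    if not records:
        raise StructureError(f"{path}: no FASTA records found")
    return records


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read ungapped FASTA; T→U and uppercase normalization applied.

    Raises :class:`StructureError` on duplicate ids, empty files, or
    residues outside {A,C,G,U,N} (reported with position).
    """
    return _read_fasta_records(path, allow_gap=False)


def read_alignment(path: str | Path) -> list[SequenceRecord]:
    """Read aligned FASTA (gap character ``-``); all rows must share a length.

    ``.`` is rejected as a gap character to avoid confusion with the
    dot-bracket notation used elsewhere in the pipeline.
    """
    records = _read_fasta_records(path, allow_gap=True)
    width = len(records[0])
    for rec in records:
        if len(rec) != width:
            raise StructureError(
                f"ragged alignment: row {rec.id!r} has length {len(rec)}, "
                f"expected {width}"
            )
    return records


# ---------------------------------------------------------------------------
# CT (Mfold / RNAstructure)

_CT_HEADER_RE = re.compile(r"^\s*(\d+)")


def read_ct(path: str | Path) -> AnnotatedStructure:
    """Read a connectivity-table (CT) file as written by Mfold/RNAstructure.

    Only the sequence and the pairing column are used; thermodynamic detail
    in the header is ignored. Pairing must be mutual and pseudoknot-free.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = [ln.rstrip("\r\n") for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise StructureError(f"{path}: empty CT file")
    m = _CT_HEADER_RE.match(lines[0])
    if m is None:
        raise StructureError(f"{path}: CT header lacks a length field")
    n = int(m.group(1))
    body = lines[1 : 1 + n]
    if len(body) < n:
        raise StructureError(
            f"{path}: header declares {n} bases but only {len(body)} lines follow"
        )
    seq_chars: list[str] = []
    partner: dict[int, int] = {}
    for expected_i, ln in enumerate(body, start=1):
        fields = ln.split()
        if len(fields) < 5:
            raise StructureError(f"{path}: malformed CT line: {ln!r}")
        i = int(fields[0])
        if i != expected_i:
            raise StructureError(
                f"{path}: CT line numbering jumps to {i}, expected {expected_i}"
            )
        base = _normalize(fields[1])
        _validate_residues(base, label=f"{path.name} line {i}")
        seq_chars.append(base)
        j = int(fields[4])
        if j:
            partner[i] = j
    pairs: set[tuple[int, int]] = set()
    for i, j in partner.items():
        if not (1 <= j <= n):
            raise StructureError(f"{path}: position {i} pairs to {j}, out of range")
        if partner.get(j) != i:
            raise StructureError(
                f"{path}: inconsistent pairing — {i} points to {j} but {j} "
                f"points to {partner.get(j, 0)}"
            )
        if i < j:
            pairs.add((i, j))
    rec = SequenceRecord(id=path.stem, seq="".join(seq_chars), source=str(path))
    return AnnotatedStructure(record=rec, pairs=frozenset(pairs))


# ---------------------------------------------------------------------------
# Vienna dot-bracket


def parse_dotbracket(structure: str) -> frozenset[tuple[int, int]]:
    """Turn a ``(``/``)``/``.`` string into a 1-based pair set."""
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(
                    f"unbalanced bracket: ')' at position {pos} has no opener"
                )
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise StructureError(
                f"invalid structure character {ch!r} at position {pos}"
            )
    if stack:
        raise StructureError(
            f"unbalanced bracket: '(' at position {stack[-1]} is never closed"
        )
    return frozenset(pairs)


def dotbracket(struct: AnnotatedStructure) -> str:
    """Render a structure's pair set as a dot-bracket string."""
    chars = ["."] * len(struct)
    for i, j in struct.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def read_vienna(path: str | Path) -> AnnotatedStructure | list[AnnotatedStructure]:
    """Read Vienna records of (header, sequence, dot-bracket).

    Returns a single structure if the file holds one record, else a list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    structs: list[AnnotatedStructure] = []
    idx = 0
    while idx < len(lines):
        header = lines[idx]
        if not header.startswith(">"):
            raise StructureError(f"{path}: expected FASTA-style header, got {header!r}")
        if idx + 2 >= len(lines):
            raise StructureError(f"{path}: truncated record {header!r}")
        seq = _normalize(lines[idx + 1])
        db = lines[idx + 2].split()[0]  # tolerate trailing energy annotation
        if len(db) != len(seq):
            raise StructureError(
                f"{path}: structure length {len(db)} != sequence length {len(seq)} "
                f"for record {header[1:]!r}"
            )
        _validate_residues(seq, label=f"{path.name}:{header[1:]}")
        rec = SequenceRecord(id=header[1:].split()[0], seq=seq, source=str(path))
        structs.append(
            AnnotatedStructure(record=rec, pairs=parse_dotbracket(db))
        )
        idx += 3
    if not structs:
        raise StructureError(f"{path}: no Vienna records found")
    return structs[0] if len(structs) == 1 else structs


def write_vienna(
    structs: AnnotatedStructure | Iterable[AnnotatedStructure], path: str | Path
) -> None:
    """Write one or more structures in Vienna dot-bracket format.

    Round-trips exactly: ``read_vienna(write_vienna(s))`` reproduces the
    sequence and pair set of ``s``.
    """
    if isinstance(structs, AnnotatedStructure):
        structs = [structs]
    out = []
    for s in structs:
        out.append(f">{s.id}\n{s.seq}\n{dotbracket(s)}\n")
    Path(path).write_text("".join(out))
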