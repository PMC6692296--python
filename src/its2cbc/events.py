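"""Classification of base-pair changes between homologous structures.

This is the analytical core: every homologous base-pair column is classified
as identical, compensatory (CBC — both partners change, pairing retained),
hemi-compensatory (HCBC — one partner changes, pairing retained), a pairing
loss/gain, a substitution inside an already-mismatched site, or an indel.
Aggregation produces per-strain-pair counts, pairwise CBC/HCBC matrices
across a family of strains, and the two small-subunit (SSU) alignment
utilities: variable-position counting and insertion-block (intron) detection.

A CBC requires pairing capability on both sides; Watson–Crick pairs and the
G·U / U·G wobbles count as pairing-capable, mismatches and N-containing
pairs do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .alignment import (
    HomologousPairTable,
    PairwiseAlignment,
    ScoringConfig,
    align_pair,
    identity_alignment,
    map_homologous_pairs,
)
from .io import AnnotatedStructure, Region, SequenceRecord, StructureError

__all__ = [
    "PairCategory",
    "PairState",
    "ChangeKlass",
    "ChangeEvent",
    "ChangeCounts",
    "CBCMatrix",
    "classify_pair_state",
    "classify_change",
    "count_events",
    "events_table",
    "cbc_matrix",
    "count_variable_positions",
    "detect_insertion_blocks",
]

CANONICAL = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
WOBBLE = frozenset({("G", "U"), ("U", "G")})
_BASES = frozenset("ACGUN-")


class PairCategory(str, Enum):
    CANONICAL = "canonical"
    WOBBLE = "wobble"
    MISMATCH = "mismatch"
    GAPPED = "gapped"
    UNPAIRED = "unpaired"


@dataclass(frozen=True)
class PairState:
    """The two residues at a (putative) base-pair site, 5′ partner first."""

    n5: str
    n3: str
    category: PairCategory

    @property
    def pairing_capable(self) -> bool:
        return self.category in (PairCategory.CANONICAL, PairCategory.WOBBLE)


def classify_pair_state(n5: str, n3: str, *, paired: bool = True) -> PairState:
    """Categorize an ordered residue pair.

    N never forms a pair (a conservative rule: ambiguous reads must not
    inflate compensatory-change counts). ``paired=False`` marks positions
    outside any base pair as ``unpaired`` regardless of their residues.
    """
    if n5 not in _BASES or n3 not in _BASES:
        bad = n5 if n5 not in _BASES else n3
        raise StructureError(f"residue {bad!r} outside alphabet {{A,C,G,U,N,-}}")
    if n5 == "-" or n3 == "-":
        cat = PairCategory.GAPPED
    elif not paired:
        cat = PairCategory.UNPAIRED
    elif (n5, n3) in CANONICAL:
        cat = PairCategory.CANONICAL
    elif (n5, n3) in WOBBLE:
        cat = PairCategory.WOBBLE
    else:
        cat = PairCategory.MISMATCH
    return PairState(n5=n5, n3=n3, category=cat)


class ChangeKlass(str, Enum):
    IDENTICAL = "identical"
    CBC = "CBC"
    HCBC = "HCBC"
    PAIRING_LOST = "pairing_lost"
    PAIRING_GAINED = "pairing_gained"
    SUBSTITUTION_IN_MISMATCH = "substitution_in_mismatch"
    INDEL = "indel"


@dataclass(frozen=True)
class ChangeEvent:
    """Per-column classification of the change between two strains."""

    columns: tuple[int, int]
    state_a: PairState
    state_b: PairState
    klass: ChangeKlass


def classify_change(state_a: PairState, state_b: PairState) -> ChangeKlass:
    """Decision table for one homologous base-pair site.

    Identity is checked first: same residues on both sides with the same
    pairing status is never an event (identical residues where only one
    strain actually pairs are a pairing loss/gain, not an identity); a gap
    on either side is an indel; with
    both sides pairing-capable a two-sided residue change is a CBC and a
    one-sided change an HCBC; pairing present on exactly one side is a
    pairing loss/gain; the remainder are substitutions between non-pairing
    states. Total on valid states.
    """
    a_pc, b_pc = state_a.pairing_capable, state_b.pairing_capable
    if state_a.n5 == state_b.n5 and state_a.n3 == state_b.n3 and a_pc == b_pc:
        return ChangeKlass.IDENTICAL
    if state_a.category is PairCategory.GAPPED or state_b.category is PairCategory.GAPPED:
        return ChangeKlass.INDEL
    if a_pc and b_pc:
        if state_a.n5 != state_b.n5 and state_a.n3 != state_b.n3:
            return ChangeKlass.CBC
        return ChangeKlass.HCBC
    if a_pc and not b_pc:
        return ChangeKlass.PAIRING_LOST
    if b_pc and not a_pc:
        return ChangeKlass.PAIRING_GAINED
    return ChangeKlass.SUBSTITUTION_IN_MISMATCH


@dataclass
class ChangeCounts:
    """Aggregated event counts for one strain pair and region."""

    id_a: str
    id_b: str
    region: str = "all"
    counts: dict[ChangeKlass, int] = field(
        default_factory=lambda: {k: 0 for k in ChangeKlass}
    )
    events: list[ChangeEvent] = field(default_factory=list)

    def __getitem__(self, klass: ChangeKlass) -> int:
        return self.counts[klass]

    @property
    def n_compared(self) -> int:
        return sum(self.counts.values())

    @property
    def cbc(self) -> int:
        return self.counts[ChangeKlass.CBC]

    @property
    def hcbc(self) -> int:
        return self.counts[ChangeKlass.HCBC]


def _row_event(
    a: AnnotatedStructure,
    b: AnnotatedStructure,
    pos_a: dict[int, int | None],
    pos_b: dict[int, int | None],
    row,
) -> ChangeEvent:
    ci, cj = row.columns

    def state(struct: AnnotatedStructure, pair, pos_of_col) -> PairState:
        if pair is not None:
            return classify_pair_state(struct.record.base(pair[0]), struct.record.base(pair[1]))
        pi, pj = pos_of_col.get(ci), pos_of_col.get(cj)
        n5 = struct.record.base(pi) if pi is not None else "-"
        n3 = struct.record.base(pj) if pj is not None else "-"
        return classify_pair_state(n5, n3, paired=False)

    sa = state(a, row.pair_a, pos_a)
    sb = state(b, row.pair_b, pos_b)
    return ChangeEvent(columns=(ci, cj), state_a=sa, state_b=sb, klass=classify_change(sa, sb))


def count_events(
    a: AnnotatedStructure,
    b: AnnotatedStructure,
    table: HomologousPairTable,
    aln: PairwiseAlignment,
    region: tuple[int, int] | None = None,
    region_name: str = "all",
) -> ChangeCounts:
    """Classify every homologous-pair row and aggregate counts per class.

    ``region`` is a 0-based inclusive window in alignment columns; a row
    belongs to the region iff its 5′ column lies inside it. Rows where only
    one structure has a pair are classified through the partner's residues
    at the same columns (unpaired → pairing loss/gain, gap → indel).
    """
    if table.id_a != a.id or table.id_b != b.id:
        raise StructureError("homologous-pair table labels do not match structures")
    pos_a = {c: p for c, p in enumerate(aln.cols_a)}
    pos_b = {c: p for c, p in enumerate(aln.cols_b)}
    out = ChangeCounts(id_a=a.id, id_b=b.id, region=region_name)
    for row in table.rows:
        if region is not None and not (region[0] <= row.columns[0] <= region[1]):
            continue
        ev = _row_event(a, b, pos_a, pos_b, row)
        out.counts[ev.klass] += 1
        out.events.append(ev)
    if region is not None and not out.events:
        warnings.warn(
            f"region {region_name!r} contains no base-pair columns for "
            f"({a.id}, {b.id}); returning zero counts",
            stacklevel=2,
        )
    return out


def events_table(counts: ChangeCounts) -> pd.DataFrame:
    """Per-column event table (TSV-ready) for one strain pair."""
    return pd.DataFrame(
        {
            "ci": [e.columns[0] for e in counts.events],
            "cj": [e.columns[1] for e in counts.events],
            "stateA": [f"{e.state_a.n5}-{e.state_a.n3}" for e in counts.events],
            "stateB": [f"{e.state_b.n5}-{e.state_b.n3}" for e in counts.events],
            "klass": [e.klass.value for e in counts.events],
        }
    )


# ---------------------------------------------------------------------------
# Family-level matrix via star alignment through a reference


@dataclass
class CBCMatrix:
    """Pairwise CBC and HCBC count matrices over a family of strains."""

    ids: tuple[str, ...]
    cbc: pd.DataFrame
    hcbc: pd.DataFrame

    def cbc_count(self, a: str, b: str) -> int:
        return int(self.cbc.loc[a, b])

    def hcbc_count(self, a: str, b: str) -> int:
        return int(self.hcbc.loc[a, b])


def _star_frames(
    structs: list[AnnotatedStructure],
    reference_id: str,
    params: ScoringConfig | None,
) -> tuple[AnnotatedStructure, dict[str, dict[int, int]]]:
    """Align every strain to the reference; return ref-position → strain-position maps."""
    by_id = {s.id: s for s in structs}
    if reference_id not in by_id:
        raise StructureError(f"reference id {reference_id!r} not among inputs")
    ref = by_id[reference_id]
    frames: dict[str, dict[int, int]] = {}
    for s in structs:
        if s.id == reference_id:
            frames[s.id] = {i: i for i in range(1, len(ref) + 1)}
            continue
        aln = align_pair(ref, s, params)
        frame: dict[int, int] = {}
        for pr, ps in zip(aln.cols_a, aln.cols_b):
            if pr is not None and ps is not None:
                frame[pr] = ps
        frames[s.id] = frame
    return ref, frames


def cbc_matrix(
    structs: list[AnnotatedStructure],
    reference_id: str | None = None,
    region: Region | tuple[int, int] | None = None,
    params: ScoringConfig | None = None,
) -> CBCMatrix:
    """Count CBCs and HCBCs for every unordered strain pair.

    All strains are placed into the reference's coordinate frame by star-wise
    pairwise alignment (reference defaults to the first input), so the same
    region window applies to every comparison and the matrices are symmetric
    by construction. ``region`` is given in reference coordinates (1-based
    inclusive); base pairs that do not anchor to reference coordinates are
    compared only in the unrestricted (region=None) mode, where they count
    as indel-class sites.
    """
    if len(structs) < 2:
        raise StructureError("need at least two structures")
    ids = tuple(s.id for s in structs)
    if len(set(ids)) != len(ids):
        raise StructureError("duplicate structure ids")
    reference_id = reference_id or ids[0]
    ref, frames = _star_frames(structs, reference_id, params)

    if isinstance(region, Region):
        window: tuple[int, int] | None = (region.start, region.end)
    else:
        window = region

    by_id = {s.id: s for s in structs}
    # project each strain's pairs into reference coordinates
    proj: dict[str, dict[tuple[int, int], tuple[int, int]]] = {}
    unanchored: dict[str, int] = {}
    for sid, frame in frames.items():
        inv = {v: k for k, v in frame.items()}  # strain pos -> ref pos
        pmap: dict[tuple[int, int], tuple[int, int]] = {}
        lost = 0
        for i, j in sorted(by_id[sid].pairs):
            ri, rj = inv.get(i), inv.get(j)
            if ri is None or rj is None:
                lost += 1
                continue
            pmap[(ri, rj)] = (i, j)
        proj[sid] = pmap
        unanchored[sid] = lost

    order = sorted(ids)
    cbc = pd.DataFrame(0, index=order, columns=order, dtype=int)
    hcbc = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for x_pos, sid_x in enumerate(order):
        for sid_y in order[x_pos + 1 :]:
            keys = set(proj[sid_x]) | set(proj[sid_y])
            n_cbc = n_hcbc = 0
            for ri, rj in keys:
                if window is not None and not (window[0] <= ri <= window[1]):
                    continue
                sx = _state_in_frame(by_id[sid_x], frames[sid_x], proj[sid_x], (ri, rj))
                sy = _state_in_frame(by_id[sid_y], frames[sid_y], proj[sid_y], (ri, rj))
                k = classify_change(sx, sy)
                if k is ChangeKlass.CBC:
                    n_cbc += 1
                elif k is ChangeKlass.HCBC:
                    n_hcbc += 1
            cbc.loc[sid_x, sid_y] = cbc.loc[sid_y, sid_x] = n_cbc
            hcbc.loc[sid_x, sid_y] = hcbc.loc[sid_y, sid_x] = n_hcbc
    return CBCMatrix(ids=tuple(order), cbc=cbc, hcbc=hcbc)


def _state_in_frame(
    struct: AnnotatedStructure,
    frame: dict[int, int],
    pmap: dict[tuple[int, int], tuple[int, int]],
    ref_key: tuple[int, int],
) -> PairState:
    pair = pmap.get(ref_key)
    if pair is not None:
        return classify_pair_state(struct.record.base(pair[0]), struct.record.base(pair[1]))
    pi, pj = frame.get(ref_key[0]), frame.get(ref_key[1])
    n5 = struct.record.base(pi) if pi is not None else "-"
    n3 = struct.record.base(pj) if pj is not None else "-"
    return classify_pair_state(n5, n3, paired=False)


# ---------------------------------------------------------------------------
# SSU alignment utilities


def count_variable_positions(
    alignment: list[SequenceRecord],
    taxa: list[str] | None = None,
    gap_policy: str = "ignore-gaps",
) -> tuple[int, list[int]]:
    """Count alignment columns variable among a taxon subset.

    A column is variable iff at least two distinct residues occur among the
    chosen rows; under the default ``ignore-gaps`` policy gaps are not a
    state, under ``gaps-as-state`` they are. Positions are reported 1-based
    in alignment coordinates.
    """
    if gap_policy not in ("ignore-gaps", "gaps-as-state"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    by_id = {r.id: r for r in alignment}
    if taxa is None:
        rows = alignment
    else:
        missing = [t for t in taxa if t not in by_id]
        if missing:
            raise StructureError(f"unknown taxon id(s): {missing}")
        rows = [by_id[t] for t in taxa]
    if not rows:
        raise StructureError("empty taxon subset")
    width = len(rows[0])
    positions: list[int] = []
    for c in range(width):
        states = {r.seq[c] for r in rows}
        if gap_policy == "ignore-gaps":
            states.discard("-")
        if len(states) >= 2:
            positions.append(c + 1)
    return len(positions), positions


@dataclass(frozen=True)
class InsertionBlock:
    """A maximal run of columns present only in the carrier rows."""

    start: int  # 1-based alignment column
    length: int
    carriers: tuple[str, ...]


def detect_insertion_blocks(
    alignment: list[SequenceRecord],
    carriers: list[str],
    min_length: int = 50,
) -> list[InsertionBlock]:
    """Find long carrier-only insertions (e.g. group I introns) in an alignment.

    A block is a maximal run of columns that are residues in every carrier
    row and gaps in every non-carrier row, of length at least ``min_length``
    (default 50 — long enough to exclude ordinary indel scatter, far below
    any group I intron).
    """
    ids = [r.id for r in alignment]
    if not set(carriers) <= set(ids) or not carriers or set(carriers) == set(ids):
        raise StructureError(
            "carriers must be a non-empty proper subset of the alignment rows"
        )
    carrier_rows = [r for r in alignment if r.id in set(carriers)]
    other_rows = [r for r in alignment if r.id not in set(carriers)]
    width = len(alignment[0])
    blocks: list[InsertionBlock] = []
    run_start: int | None = None
    for c in range(width + 1):
        in_block = (
            c < width
            and all(r.seq[c] != "-" for r in carrier_rows)
            and all(r.seq[c] == "-" for r in other_rows)
        )
        if in_block and run_start is None:
            run_start = c
        elif not in_block and run_start is not None:
            length = c - run_start
            if length >= min_length:
                blocks.append(
                    InsertionBlock(
                        start=run_start + 1,
                        length=length,
                        carriers=tuple(sorted(carriers)),
                    )
                )
            run_start = None
    return blocks
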