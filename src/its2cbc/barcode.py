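"""The 1–8 number-code barcode of ITS-2 base pairs and barcode comparison.

Each base pair of a structure region is translated into a single digit that
encodes its identity and orientation:

    1 = A–U   2 = U–A   3 = G–C   4 = C–G   5 = G·U   6 = U·G
    7 = mismatch        8 = deletion / single (unpaired) bases

The code is emitted once per pair, at the pair's 5′ column (the orientation
distinction between A–U and U–A carries the 3′ side implicitly); unpaired
and gapped columns emit 8. Barcode differences are annotated per column as
CBC, HCBC, insertion/deletion (I/D) or other, mirroring the asterisk
markup used when barcodes are presented side by side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .alignment import PairwiseAlignment
from .events import (
    ChangeKlass,
    PairCategory,
    PairState,
    classify_change,
    classify_pair_state,
)
from .io import AnnotatedStructure, Region, StructureError

__all__ = [
    "CODE_OF_PAIR",
    "Barcode",
    "BarcodeDiff",
    "encode_column",
    "encode_barcode",
    "compare_barcodes",
    "barcode_table",
    "diff_table",
]

#: The six pairing-capable ordered pair types and their digits.
CODE_OF_PAIR = {
    ("A", "U"): 1,
    ("U", "A"): 2,
    ("G", "C"): 3,
    ("C", "G"): 4,
    ("G", "U"): 5,
    ("U", "G"): 6,
}

MISMATCH_CODE = 7
UNPAIRED_CODE = 8


def encode_column(state: PairState) -> int:
    """Digit for one pair state: 1–6 for pairs, 7 for mismatch, 8 otherwise."""
    if state.category in (PairCategory.CANONICAL, PairCategory.WOBBLE):
        return CODE_OF_PAIR[(state.n5, state.n3)]
    if state.category is PairCategory.MISMATCH:
        return MISMATCH_CODE
    return UNPAIRED_CODE  # gapped, unpaired


@dataclass(frozen=True)
class Barcode:
    """A region's number-code barcode with traceability back to columns.

    ``codes[k]`` is the digit emitted at alignment column ``columns[k]``
    (0-based); for pair codes, ``partners[k]`` is the 3′ partner's column
    and ``states[k]`` the underlying :class:`PairState`.
    """

    strain_id: str
    region_name: str
    codes: tuple[int, ...]
    columns: tuple[int, ...]
    partners: tuple[int | None, ...]
    states: tuple[PairState, ...]
    span: tuple[int, int] = (0, 0)  # 0-based inclusive column window encoded

    def __post_init__(self) -> None:
        if not all(1 <= c <= 8 for c in self.codes):
            raise StructureError("barcode digits must lie in 1..8")
        if not (
            len(self.codes) == len(self.columns) == len(self.partners) == len(self.states)
        ):
            raise StructureError("barcode field lengths disagree")

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def digits(self) -> str:
        """Compact digit-string form, e.g. ``'33158...'``."""
        return "".join(str(c) for c in self.codes)


def encode_barcode(
    struct: AnnotatedStructure,
    region: Region | tuple[int, int] | str | None = None,
    aln: PairwiseAlignment | None = None,
    region_name: str | None = None,
) -> Barcode:
    """Translate a structure region into its number-code barcode.

    ``region`` is 1-based inclusive in alignment columns (or a named region
    of the structure, resolved through ``aln`` when one is given; without an
    alignment, columns equal sequence positions). Each base pair contributes
    one digit at its 5′ column; the 3′ columns of pairs are omitted; columns
    that are unpaired or gapped contribute 8.
    """
    if isinstance(region, str):
        region = struct.region(region)
    if isinstance(region, Region):
        region_name = region_name or region.name
        span = (region.start, region.end)
    elif region is None:
        span = None
    else:
        span = region
    region_name = region_name or "all"

    if aln is None:
        n_cols = len(struct)
        pos_of_col = {c: c + 1 for c in range(n_cols)}
        col_of_pos = {p: p - 1 for p in range(1, n_cols + 1)}
    else:
        n_cols = len(aln)
        pos_of_col = {c: p for c, p in enumerate(aln.cols_a) if p is not None}
        col_of_pos = {p: c for c, p in pos_of_col.items()}

    if span is None:
        lo, hi = 0, n_cols - 1
    else:
        lo, hi = span[0] - 1, span[1] - 1
        if lo < 0 or hi >= n_cols or lo > hi:
            raise StructureError(f"region {span} outside alignment frame (1..{n_cols})")

    partner = struct.partner_map()
    codes: list[int] = []
    columns: list[int] = []
    partners: list[int | None] = []
    states: list[PairState] = []
    for c in range(lo, hi + 1):
        pos = pos_of_col.get(c)
        if pos is None:
            st = classify_pair_state("-", "-", paired=False)
            codes.append(UNPAIRED_CODE)
            columns.append(c)
            partners.append(None)
            states.append(st)
            continue
        mate = partner.get(pos)
        if mate is None:
            st = classify_pair_state(struct.record.base(pos), "-", paired=False)
            codes.append(UNPAIRED_CODE)
            columns.append(c)
            partners.append(None)
            states.append(st)
        elif mate > pos:  # 5′ side of a pair: emit the pair's digit here
            st = classify_pair_state(struct.record.base(pos), struct.record.base(mate))
            codes.append(encode_column(st))
            columns.append(c)
            partners.append(col_of_pos[mate])
            states.append(st)
        # 3′ side of a pair: omitted — the pair was coded at its 5′ column
    return Barcode(
        strain_id=struct.id,
        region_name=region_name,
        codes=tuple(codes),
        columns=tuple(columns),
        partners=tuple(partners),
        states=tuple(states),
        span=(lo, hi),
    )


@dataclass(frozen=True)
class BarcodeDiff:
    """Column-wise comparison of two equal-frame barcodes."""

    id_a: str
    id_b: str
    annotations: tuple[str, ...]  # per column: same | CBC | HCBC | I/D | other
    columns: tuple[int, ...]
    summary: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.annotations)


def compare_barcodes(b1: Barcode, b2: Barcode) -> BarcodeDiff:
    """Annotate differences between two barcodes over the same region/frame.

    Per column: ``same`` when the digits agree; ``CBC``/``HCBC`` when both
    digits are pair codes (1–6)
    and the residues differ on both/one side; ``I/D`` when exactly one digit
    is 8; ``other`` for everything else (e.g. a mismatch code 7 against a
    pair code — changes touching a non-pairing state are not compensatory).

    When the two structures disagree on which columns are paired, their
    emitted column sets differ (3′ pair columns are omitted per structure);
    the comparison then walks the union of emitted columns, with a column
    that is the 3′ side of a pair inheriting that pair's digit and a column
    absent from a barcode reading as 8 — this is what turns a pair present
    in only one strain into I/D annotations.
    """
    if b1.span != b2.span:
        raise StructureError(
            f"barcodes cover different column windows ({b1.span} vs {b2.span}); "
            "encode both in the same region and frame before comparing"
        )
    if b1.columns == b2.columns:
        cols = list(b1.columns)
        view1 = list(zip(b1.codes, b1.states))
        view2 = list(zip(b2.codes, b2.states))
    else:
        cols = sorted(set(b1.columns) | set(b2.columns))
        view1 = [_code_at(b1, c) for c in cols]
        view2 = [_code_at(b2, c) for c in cols]
    annotations: list[str] = []
    summary = {"same": 0, "CBC": 0, "HCBC": 0, "I/D": 0, "other": 0}
    for (c1, s1), (c2, s2) in zip(view1, view2):
        if c1 == c2:
            ann = "same"
        elif 1 <= c1 <= 6 and 1 <= c2 <= 6:
            klass = classify_change(s1, s2)
            if klass is ChangeKlass.CBC:
                ann = "CBC"
            elif klass is ChangeKlass.HCBC:
                ann = "HCBC"
            else:
                ann = "other"
        elif (c1 == UNPAIRED_CODE) != (c2 == UNPAIRED_CODE):
            ann = "I/D"
        else:
            ann = "other"
        annotations.append(ann)
        summary[ann] += 1
    return BarcodeDiff(
        id_a=b1.strain_id,
        id_b=b2.strain_id,
        annotations=tuple(annotations),
        columns=tuple(cols),
        summary=summary,
    )


def _code_at(bc: Barcode, col: int) -> tuple[int, PairState]:
    """Digit and state of a barcode at an arbitrary column (union walk)."""
    try:
        k = bc.columns.index(col)
    except ValueError:
        pass
    else:
        return bc.codes[k], bc.states[k]
    for k, partner in enumerate(bc.partners):
        if partner == col:  # 3′ side of a pair: inherit the pair's digit
            return bc.codes[k], bc.states[k]
    return UNPAIRED_CODE, classify_pair_state("-", "-", paired=False)


def barcode_table(bc: Barcode) -> pd.DataFrame:
    """TSV-ready table: 1-based column, digit, 1-based partner column."""
    return pd.DataFrame(
        {
            "column": [c + 1 for c in bc.columns],
            "code": list(bc.codes),
            "partner_column": [None if p is None else p + 1 for p in bc.partners],
        }
    )


def diff_table(b1: Barcode, b2: Barcode, diff: BarcodeDiff) -> pd.DataFrame:
    """Side-by-side digits with asterisks marking every difference column."""
    return pd.DataFrame(
        {
            "column": [c + 1 for c in diff.columns],
            b1.strain_id: list(b1.codes),
            b2.strain_id: list(b2.codes),
            "annotation": list(diff.annotations),
            "mark": ["" if a == "same" else "*" for a in diff.annotations],
        }
    )
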