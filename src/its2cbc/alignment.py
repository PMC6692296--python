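"""Structure-aware global pairwise alignment and homologous-pair mapping.

The comparison of base pairs between strains needs a column correspondence
between their structures. This module provides a deterministic
Needleman–Wunsch/Gotoh global aligner with affine gaps plus a constant
bonus for aligning two paired positions, and the projection of each
structure's pair set into shared alignment columns (the homologous-pair
table every downstream count is built on). Users with an external
structural alignment can bypass the aligner entirely and supply aligned
FASTA via :func:`its2cbc.io.read_alignment`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import AnnotatedStructure, Region, StructureError

__all__ = [
    "ScoringConfig",
    "PairwiseAlignment",
    "HomologousRow",
    "HomologousPairTable",
    "align_pair",
    "identity_alignment",
    "alignment_from_gapped",
    "map_homologous_pairs",
    "project_region",
]


@dataclass(frozen=True)
class ScoringConfig:
    """Alignment scores. A gap of length L costs ``gap_open + L*gap_extend``.

    ``structure_bonus`` is added to the substitution score whenever both
    aligned positions are paired in their own structures; it nudges the
    aligner to stack conserved helices on top of each other without
    forbidding sequence-driven placements.
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    structure_bonus: float = 1.0


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences as per-column source indices.

    ``cols_a[c]`` is the 1-based position of A in alignment column ``c``
    (0-based), or ``None`` where A is gapped; likewise ``cols_b``. Non-gap
    indices are strictly increasing and every source position appears in
    exactly one column.
    """

    id_a: str
    id_b: str
    cols_a: tuple[int | None, ...]
    cols_b: tuple[int | None, ...]
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.cols_a) != len(self.cols_b):
            raise StructureError("alignment rows differ in length")
        for cols in (self.cols_a, self.cols_b):
            prev = 0
            for x in cols:
                if x is None:
                    continue
                if x != prev + 1:
                    raise StructureError(
                        "alignment columns must enumerate source positions "
                        f"in order: got {x} after {prev}"
                    )
                prev = x

    def __len__(self) -> int:
        return len(self.cols_a)

    def col_of_a(self) -> dict[int, int]:
        """Map 1-based A positions to 0-based alignment columns."""
        return {p: c for c, p in enumerate(self.cols_a) if p is not None}

    def col_of_b(self) -> dict[int, int]:
        return {p: c for c, p in enumerate(self.cols_b) if p is not None}


def identity_alignment(a: AnnotatedStructure, b: AnnotatedStructure) -> PairwiseAlignment:
    """The trivial column-per-position alignment of two equal-length structures."""
    if len(a) != len(b):
        raise StructureError(
            f"identity alignment requires equal lengths ({len(a)} vs {len(b)})"
        )
    idx = tuple(range(1, len(a) + 1))
    return PairwiseAlignment(id_a=a.id, id_b=b.id, cols_a=idx, cols_b=idx)


def alignment_from_gapped(
    row_a: str, row_b: str, *, id_a: str = "A", id_b: str = "B"
) -> PairwiseAlignment:
    """Build a :class:`PairwiseAlignment` from two gapped alignment rows."""
    if len(row_a) != len(row_b):
        raise StructureError("gapped rows differ in length")
    cols_a: list[int | None] = []
    cols_b: list[int | None] = []
    pa = pb = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-":
            cols_a.append(None)
        else:
            pa += 1
            cols_a.append(pa)
        if cb == "-":
            cols_b.append(None)
        else:
            pb += 1
            cols_b.append(pb)
    return PairwiseAlignment(id_a=id_a, id_b=id_b, cols_a=tuple(cols_a), cols_b=tuple(cols_b))


def align_pair(
    a: AnnotatedStructure,
    b: AnnotatedStructure,
    params: ScoringConfig | None = None,
) -> PairwiseAlignment:
    """Global alignment of two structures (Gotoh affine-gap DP).

    The substitution score for aligning A's position i with B's position j is
    match/mismatch on the residues plus ``structure_bonus`` when both i and j
    are paired in their own structures. Tie-breaking is fixed — diagonal over
    up (gap in B) over left (gap in A) — so the output is byte-reproducible.
    """
    p = params or ScoringConfig()
    sa, sb = a.seq, b.seq
    n, m = len(sa), len(sb)
    if n == 0 or m == 0:
        raise StructureError("cannot align an empty sequence")
    paired_a = {i for ij in a.pairs for i in ij}
    paired_b = {i for ij in b.pairs for i in ij}

    NEG = float("-inf")
    # States: M — i aligned to j; X — gap in B (A residue against '-');
    # Y — gap in A. Pointer matrices record the chosen predecessor state,
    # with ties broken in the fixed order M > X > Y (diagonal > up > left).
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    PM = [[""] * (m + 1) for _ in range(n + 1)]
    PX = [[""] * (m + 1) for _ in range(n + 1)]
    PY = [[""] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = p.gap_open + i * p.gap_extend
        PX[i][0] = "M" if i == 1 else "X"
    for j in range(1, m + 1):
        Y[0][j] = p.gap_open + j * p.gap_extend
        PY[0][j] = "M" if j == 1 else "Y"

    go_ge = p.gap_open + p.gap_extend
    for i in range(1, n + 1):
        ai = sa[i - 1]
        a_paired = i in paired_a
        for j in range(1, m + 1):
            s = p.match if ai == sb[j - 1] else p.mismatch
            if a_paired and j in paired_b:
                s += p.structure_bonus
            # M: best predecessor among M, X, Y at (i-1, j-1)
            best, ptr = M[i - 1][j - 1], "M"
            if X[i - 1][j - 1] > best:
                best, ptr = X[i - 1][j - 1], "X"
            if Y[i - 1][j - 1] > best:
                best, ptr = Y[i - 1][j - 1], "Y"
            M[i][j] = best + s
            PM[i][j] = ptr
            # X: open from M/Y or extend from X, at (i-1, j)
            best, ptr = M[i - 1][j] + go_ge, "M"
            if X[i - 1][j] + p.gap_extend > best:
                best, ptr = X[i - 1][j] + p.gap_extend, "X"
            if Y[i - 1][j] + go_ge > best:
                best, ptr = Y[i - 1][j] + go_ge, "Y"
            X[i][j] = best
            PX[i][j] = ptr
            # Y: open from M/X or extend from Y, at (i, j-1)
            best, ptr = M[i][j - 1] + go_ge, "M"
            if X[i][j - 1] + go_ge > best:
                best, ptr = X[i][j - 1] + go_ge, "X"
            if Y[i][j - 1] + p.gap_extend > best:
                best, ptr = Y[i][j - 1] + p.gap_extend, "Y"
            Y[i][j] = best
            PY[i][j] = ptr

    state, score = "M", M[n][m]
    if X[n][m] > score:
        state, score = "X", X[n][m]
    if Y[n][m] > score:
        state, score = "Y", Y[n][m]

    cols_a: list[int | None] = []
    cols_b: list[int | None] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            cols_a.append(i)
            cols_b.append(j)
            state = PM[i][j]
            i, j = i - 1, j - 1
        elif state == "X":
            cols_a.append(i)
            cols_b.append(None)
            state = PX[i][j]
            i -= 1
        else:
            cols_a.append(None)
            cols_b.append(j)
            state = PY[i][j]
            j -= 1
    cols_a.reverse()
    cols_b.reverse()
    return PairwiseAlignment(
        id_a=a.id, id_b=b.id, cols_a=tuple(cols_a), cols_b=tuple(cols_b), score=score
    )


# ---------------------------------------------------------------------------
# Homologous pair table


@dataclass(frozen=True)
class HomologousRow:
    """One homologous base-pair site: columns plus the pair each structure has there."""

    columns: tuple[int, int]
    pair_a: tuple[int, int] | None
    pair_b: tuple[int, int] | None


@dataclass(frozen=True)
class HomologousPairTable:
    """All base pairs of two structures projected to shared alignment columns.

    Two pairs share a row iff both their endpoints occupy the same alignment
    columns; every pair of either structure appears in exactly one row.
    """

    id_a: str
    id_b: str
    rows: tuple[HomologousRow, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.rows)


def map_homologous_pairs(
    a: AnnotatedStructure,
    b: AnnotatedStructure,
    aln: PairwiseAlignment,
) -> HomologousPairTable:
    """Project both pair sets into alignment columns and merge matching rows."""
    if aln.id_a != a.id or aln.id_b != b.id:
        raise StructureError(
            f"alignment labels ({aln.id_a},{aln.id_b}) do not match "
            f"structures ({a.id},{b.id})"
        )
    col_a = aln.col_of_a()
    col_b = aln.col_of_b()
    if len(col_a) != len(a) or len(col_b) != len(b):
        raise StructureError("alignment does not cover both structures completely")

    by_cols: dict[tuple[int, int], list] = {}
    for i, j in sorted(a.pairs):
        by_cols.setdefault((col_a[i], col_a[j]), [None, None])[0] = (i, j)
    for k, l in sorted(b.pairs):
        by_cols.setdefault((col_b[k], col_b[l]), [None, None])[1] = (k, l)
    rows = tuple(
        HomologousRow(columns=cols, pair_a=pa, pair_b=pb)
        for cols, (pa, pb) in sorted(by_cols.items())
    )
    return HomologousPairTable(id_a=a.id, id_b=b.id, rows=rows)


def project_region(
    aln: PairwiseAlignment, region: Region | tuple[int, int]
) -> tuple[int, int]:
    """Map a region on sequence A (1-based inclusive) to 0-based alignment columns.

    Gapped columns falling inside the projected span are included — the
    result is a contiguous window in the alignment frame.
    """
    if isinstance(region, Region):
        start, end = region.start, region.end
    else:
        start, end = region
    col_a = aln.col_of_a()
    if start < 1 or end > len(col_a) or start > end:
        raise StructureError(
            f"region ({start},{end}) out of range for sequence of length {len(col_a)}"
        )
    return col_a[start], col_a[end]
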