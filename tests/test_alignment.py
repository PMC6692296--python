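"""Structure-aware alignment: DP optimality, symmetry, pair-table mapping."""

import itertools

import pytest

from its2cbc import (
    ScoringConfig,
    StructureError,
    align_pair,
    identity_alignment,
    map_homologous_pairs,
    project_region,
)
from its2cbc.io import Region

from conftest import structure

P = ScoringConfig()


def brute_force_best_score(a, b, p=P):
    """Exhaustive optimum over all global alignments (independent oracle).

    Alignments are enumerated as move strings (M = aligned column, X = gap
    in B, Y = gap in A); a gap run of length L costs gap_open + L*gap_extend.
    Only feasible for sequences of length <= ~8.
    """
    paired_a = {i for ij in a.pairs for i in ij}
    paired_b = {i for ij in b.pairs for i in ij}
    n, m = len(a.seq), len(b.seq)

    def score(moves):
        total, i, j = 0.0, 0, 0
        prev = ""
        for mv in moves:
            if mv == "M":
                s = p.match if a.seq[i] == b.seq[j] else p.mismatch
                if (i + 1) in paired_a and (j + 1) in paired_b:
                    s += p.structure_bonus
                total += s
                i, j = i + 1, j + 1
            elif mv == "X":
                total += p.gap_extend + (p.gap_open if prev != "X" else 0)
                i += 1
            else:
                total += p.gap_extend + (p.gap_open if prev != "Y" else 0)
                j += 1
            prev = mv
        return total

    best = float("-inf")

    def walk(i, j, moves):
        nonlocal best
        if i == n and j == m:
            best = max(best, score(moves))
            return
        if i < n and j < m:
            walk(i + 1, j + 1, moves + "M")
        if i < n:
            walk(i + 1, j, moves + "X")
        if j < m:
            walk(i, j + 1, moves + "Y")

    walk(0, 0, "")
    return best


CASES = [
    (structure("ACGU", "...."), structure("ACGU", "....")),
    (structure("ACGU", "(..)"), structure("ACGU", "(..)")),
    (structure("AAAA", "...."), structure("AAAAA", ".....")),
    (structure("GGGACC", "((..))"), structure("GGACC", "((.))")),
    (structure("ACGUAC", "......"), structure("UGCAUG", "......")),
    (structure("GCGCAA", "((..))"), structure("AAGCGC", "......")),
    (structure("AUGC", "().."), structure("A", ".")),
]


@pytest.mark.parametrize("a,b", CASES, ids=range(len(CASES)))
def test_dp_matches_exhaustive_enumeration(a, b):
    """On small instances the DP score equals the brute-force optimum."""
    got = align_pair(a, b).score
    assert got == pytest.approx(brute_force_best_score(a, b))


def test_dp_oracle_on_random_small_instances():
    import numpy as np

    rng = np.random.default_rng(42)
    bases = "ACGU"
    for _ in range(15):
        la, lb = int(rng.integers(1, 7)), int(rng.integers(1, 7))
        sa = "".join(bases[i] for i in rng.integers(0, 4, la))
        sb = "".join(bases[i] for i in rng.integers(0, 4, lb))
        a = structure(sa, "." * la, "a")
        b = structure(sb, "." * lb, "b")
        assert align_pair(a, b).score == pytest.approx(brute_force_best_score(a, b))


def test_self_alignment_is_identity(hairpin):
    aln = align_pair(hairpin, hairpin)
    assert aln.cols_a == aln.cols_b == tuple(range(1, len(hairpin) + 1))


def test_identical_hairpins_align_without_gaps():
    a = structure("GGGGGAAAAACCCCCUUUUU", "(((((.....)))))....." , "a")
    b = structure("GGGGGAAAAACCCCCUUUUU", "(((((.....)))))....." , "b")
    aln = align_pair(a, b)
    assert None not in aln.cols_a and None not in aln.cols_b


def test_score_symmetric(hairpin):
    other = structure("GGCGAAUAUGCC", "((((....))))", "x")
    assert align_pair(hairpin, other).score == pytest.approx(
        align_pair(other, hairpin).score
    )


def test_single_gap_for_length_difference():
    a = structure("AAAA", "....", "a")
    b = structure("AAAAA", ".....", "b")
    aln = align_pair(a, b)
    assert sum(x is None for x in aln.cols_a) == 1
    assert sum(x is None for x in aln.cols_b) == 0


def test_empty_sequence_rejected(hairpin):
    from its2cbc import AnnotatedStructure, SequenceRecord

    with pytest.raises(StructureError):
        SequenceRecord(id="e", seq="")


def test_structure_bonus_prefers_stacking_paired_columns():
    # Sequence ties: AA vs AA-A; the bonus pulls the pair columns together.
    a = structure("GAAAC", "(...)", "a")
    b = structure("GAAAC", "(...)", "b")
    aln = align_pair(a, b)
    assert aln.cols_a == aln.cols_b


class TestHomologousPairs:
    def test_identical_structures_full_rows(self, hairpin):
        other = structure(hairpin.seq, "((((....))))", "o")
        aln = align_pair(hairpin, other)
        tab = map_homologous_pairs(hairpin, other, aln)
        assert len(tab) == 4
        assert all(r.pair_a == r.pair_b for r in tab.rows)

    def test_pair_against_unpaired_partner(self):
        a = structure("GGAAAACCAA", ".(....)...", "a")
        b = structure("GGAAAACCAA", "..........", "b")
        aln = identity_alignment(a, b)
        tab = map_homologous_pairs(a, b, aln)
        assert len(tab) == 1
        (row,) = tab.rows
        assert row.pair_a == (2, 7) and row.pair_b is None

    def test_row_count_equals_grouped_union_oracle(self):
        """Row count equals |pairsA ∪ pairsB| grouped by shared columns."""
        import numpy as np

        rng = np.random.default_rng(7)
        for _ in range(10):
            n = 30
            # random nested structure pair via stack simulation
            def rand_struct(sid):
                db, depth = [], 0
                for k in range(n):
                    r = rng.random()
                    if r < 0.3 and depth < (n - k):
                        db.append("(")
                        depth += 1
                    elif r < 0.5 and depth > 0:
                        db.append(")")
                        depth -= 1
                    else:
                        db.append(".")
                db.extend(")" * depth)
                seq = "".join("ACGU"[i] for i in rng.integers(0, 4, len(db)))
                return structure(seq, "".join(db), sid)

            a, b = rand_struct("a"), rand_struct("b")
            if len(a) != len(b):
                continue
            aln = identity_alignment(a, b)
            tab = map_homologous_pairs(a, b, aln)
            # oracle: explicit set construction under the identity frame
            expected = {(i - 1, j - 1) for i, j in a.pairs} | {
                (i - 1, j - 1) for i, j in b.pairs
            }
            assert {r.columns for r in tab.rows} == expected
            # every pair of either structure appears in exactly one row
            assert sorted(r.pair_a for r in tab.rows if r.pair_a) == sorted(a.pairs)
            assert sorted(r.pair_b for r in tab.rows if r.pair_b) == sorted(b.pairs)

    def test_label_mismatch_rejected(self, hairpin):
        other = structure(hairpin.seq, "((((....))))", "o")
        aln = align_pair(hairpin, other)
        with pytest.raises(StructureError, match="labels"):
            map_homologous_pairs(other, hairpin, aln)


class TestProjectRegion:
    def test_identity_frame(self, hairpin):
        aln = identity_alignment(hairpin, structure(hairpin.seq, "." * 12, "o"))
        assert project_region(aln, (3, 7)) == (2, 6)

    def test_gap_in_b_does_not_move_a_columns(self):
        a = structure("ACGUACGU", "........", "a")
        b = structure("ACUACGU", ".......", "b")
        aln = align_pair(a, b)
        # region given on A; its columns are wherever A's residues sit
        start, end = project_region(aln, (3, 7))
        cols = aln.col_of_a()
        assert (start, end) == (cols[3], cols[7])

    def test_region_spanning_gap_in_a(self):
        a = structure("ACGU", "....", "a")
        b = structure("ACXGU".replace("X", "A"), ".....", "b")
        aln = align_pair(a, b)
        start, end = project_region(aln, (2, 3))
        # oracle: explicit column walk
        cols = [c for c, p in enumerate(aln.cols_a) if p in (2, 3)]
        assert (start, end) == (cols[0], cols[-1])

    def test_out_of_range(self, hairpin):
        aln = identity_alignment(hairpin, structure(hairpin.seq, "." * 12, "o"))
        with pytest.raises(StructureError, match="out of range"):
            project_region(aln, (0, 5))
        with pytest.raises(StructureError, match="out of range"):
            project_region(aln, (5, 99))

    def test_named_region(self):
        a = structure("GGGAAACCCUUU", "(((...)))...", "a", [Region("stem", 1, 9)])
        aln = identity_alignment(a, structure(a.seq, "." * 12, "o"))
        assert project_region(aln, a.region("stem")) == (0, 8)
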