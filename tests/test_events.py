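"""Change classification, counting, matrices and SSU alignment utilities."""

import itertools

import numpy as np
import pytest

from its2cbc import (
    ChangeKlass,
    EventSpec,
    FamilySpec,
    PairCategory,
    SequenceRecord,
    StructureError,
    align_pair,
    cbc_matrix,
    classify_change,
    classify_pair_state,
    count_events,
    count_variable_positions,
    detect_insertion_blocks,
    identity_alignment,
    make_family,
    make_ssu_fixture,
    map_homologous_pairs,
    mutate_with_events,
    make_template,
)

from conftest import structure


class TestClassifyPairState:
    @pytest.mark.parametrize(
        "n5,n3,cat",
        [
            ("A", "U", PairCategory.CANONICAL),
            ("U", "A", PairCategory.CANONICAL),
            ("G", "C", PairCategory.CANONICAL),
            ("C", "G", PairCategory.CANONICAL),
            ("G", "U", PairCategory.WOBBLE),
            ("U", "G", PairCategory.WOBBLE),
            ("A", "A", PairCategory.MISMATCH),
            ("C", "U", PairCategory.MISMATCH),
            ("N", "U", PairCategory.MISMATCH),
            ("A", "N", PairCategory.MISMATCH),
            ("A", "-", PairCategory.GAPPED),
            ("-", "-", PairCategory.GAPPED),
        ],
    )
    def test_categories(self, n5, n3, cat):
        assert classify_pair_state(n5, n3).category is cat

    def test_unpaired_flag(self):
        assert classify_pair_state("G", "C", paired=False).category is PairCategory.UNPAIRED

    def test_bad_residue(self):
        with pytest.raises(StructureError, match="'R'"):
            classify_pair_state("R", "A")


def oracle_classify(a5, a3, b5, b3):
    """Independently written truth table over residue quadruples.

    Written from the definitions, not from the implementation: CBC = both
    partners change with pairing kept on both sides; HCBC = one partner
    changes with pairing kept; changes into/out of pairing are losses/gains.
    """
    pairing = {"AU", "UA", "GC", "CG", "GU", "UG"}

    def can_pair(x, y):
        return x + y in pairing and "N" not in (x, y)

    if (a5, a3) == (b5, b3):
        return "identical"
    if "-" in (a5, a3, b5, b3):
        return "indel"
    a_ok, b_ok = can_pair(a5, a3), can_pair(b5, b3)
    if a_ok and b_ok:
        n_changed = (a5 != b5) + (a3 != b3)
        return "CBC" if n_changed == 2 else "HCBC"
    if a_ok:
        return "pairing_lost"
    if b_ok:
        return "pairing_gained"
    return "substitution_in_mismatch"


def test_truth_table_all_625_combinations():
    """classify_change agrees with the brute-force oracle on every state pair."""
    bases = "ACGUN"
    for a5, a3, b5, b3 in itertools.product(bases, repeat=4):
        sa = classify_pair_state(a5, a3)
        sb = classify_pair_state(b5, b3)
        assert classify_change(sa, sb).value == oracle_classify(a5, a3, b5, b3), (
            a5,
            a3,
            b5,
            b3,
        )


def test_classify_change_swap_symmetry():
    """Swapping A and B preserves the class except lost ↔ gained."""
    swap = {
        "pairing_lost": "pairing_gained",
        "pairing_gained": "pairing_lost",
    }
    bases = "ACGUN-"
    for a5, a3, b5, b3 in itertools.product(bases, repeat=4):
        sa = classify_pair_state(a5, a3)
        sb = classify_pair_state(b5, b3)
        fwd = classify_change(sa, sb).value
        rev = classify_change(sb, sa).value
        assert rev == swap.get(fwd, fwd)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        (("A", "U"), ("G", "C"), ChangeKlass.CBC),
        (("A", "U"), ("U", "G"), ChangeKlass.CBC),  # wobble result still a CBC
        (("A", "U"), ("G", "U"), ChangeKlass.HCBC),
        (("A", "U"), ("A", "U"), ChangeKlass.IDENTICAL),
        (("A", "U"), ("A", "A"), ChangeKlass.PAIRING_LOST),
        (("A", "A"), ("A", "U"), ChangeKlass.PAIRING_GAINED),
        (("A", "A"), ("C", "C"), ChangeKlass.SUBSTITUTION_IN_MISMATCH),
        (("A", "U"), ("A", "-"), ChangeKlass.INDEL),
    ],
)
def test_definitional_cases(a, b, expected):
    sa, sb = classify_pair_state(*a), classify_pair_state(*b)
    assert classify_change(sa, sb) is expected


class TestCountEvents:
    def test_self_comparison_all_identical(self, hairpin):
        other = structure(hairpin.seq, "((((....))))", "o")
        aln = align_pair(hairpin, other)
        tab = map_homologous_pairs(hairpin, other, aln)
        counts = count_events(hairpin, other, tab, aln)
        assert counts.counts[ChangeKlass.IDENTICAL] == 4
        assert counts.cbc == 0 and counts.hcbc == 0

    def test_structure_vs_fully_unpaired(self):
        a = structure("GGGAAACCC", "(((...)))", "a")
        b = structure("GGGAAACCC", ".........", "b")
        aln = identity_alignment(a, b)
        tab = map_homologous_pairs(a, b, aln)
        counts = count_events(a, b, tab, aln)
        assert counts.counts[ChangeKlass.PAIRING_LOST] == 3
        assert counts.n_compared == 3

    def test_planted_cbc_hcbc_recovered(self, default_family):
        structs, manifest = default_family
        by_id = {s.id: s for s in structs}
        a, b = by_id["s1"], by_id["s4"]
        aln = align_pair(a, b)
        tab = map_homologous_pairs(a, b, aln)
        counts = count_events(a, b, tab, aln)
        assert counts.cbc == 2
        assert counts.hcbc == 2

    def test_empty_region_warns_and_returns_zero(self, hairpin):
        other = structure(hairpin.seq, "((((....))))", "o")
        aln = align_pair(hairpin, other)
        tab = map_homologous_pairs(hairpin, other, aln)
        with pytest.warns(UserWarning, match="no base-pair columns"):
            counts = count_events(hairpin, other, tab, aln, region=(5, 7))
        assert counts.n_compared == 0


class TestCBCMatrix:
    def test_identical_structures_zero(self, hairpin):
        structs = [
            structure(hairpin.seq, "((((....))))", sid) for sid in ("a", "b", "c")
        ]
        m = cbc_matrix(structs)
        assert (m.cbc.values == 0).all() and (m.hcbc.values == 0).all()

    def test_symmetry_and_zero_diagonal(self, default_family):
        structs, _ = default_family
        m = cbc_matrix(structs)
        assert (m.cbc.values == m.cbc.values.T).all()
        assert (m.cbc.values.diagonal() == 0).all()

    def test_nonzero_only_between_groups(self, default_family):
        structs, manifest = default_family
        m = cbc_matrix(structs)
        for ga in manifest.groups:
            for gb in manifest.groups:
                for a in ga:
                    for b in gb:
                        expected = manifest.expected_cbc[a][b]
                        assert m.cbc_count(a, b) == expected
                        assert m.hcbc_count(a, b) == manifest.expected_hcbc[a][b]

    def test_input_order_invariance(self, default_family):
        structs, _ = default_family
        m1 = cbc_matrix(structs, reference_id="s1")
        m2 = cbc_matrix(list(reversed(structs)), reference_id="s1")
        assert m1.cbc.equals(m2.cbc) and m1.hcbc.equals(m2.hcbc)

    def test_missing_reference(self, default_family):
        structs, _ = default_family
        with pytest.raises(StructureError, match="reference"):
            cbc_matrix(structs, reference_id="nope")

    def test_region_restriction(self, default_family):
        structs, manifest = default_family
        ref = structs[0]
        full = cbc_matrix(structs, reference_id="s1")
        helices = [ref.region(f"helix{k}") for k in (1, 2, 3, 4)]
        total_cbc = np.zeros_like(full.cbc.values)
        for r in helices:
            part = cbc_matrix(structs, reference_id="s1", region=r)
            total_cbc = total_cbc + part.cbc.values
        # every pair lives in exactly one helix, so per-helix counts add up
        assert (total_cbc == full.cbc.values).all()


class TestVariablePositions:
    def _rows(self, seqs):
        return [SequenceRecord(id=f"r{i}", seq=s) for i, s in enumerate(seqs)]

    def test_identical_rows(self):
        n, pos = count_variable_positions(self._rows(["ACGU", "ACGU"]))
        assert (n, pos) == (0, [])

    def test_known_columns(self):
        rows = self._rows(["ACGUACGUACGUA", "ACAUACGGACGCA"])
        n, pos = count_variable_positions(rows)
        assert (n, pos) == (3, [3, 8, 12])

    def test_gap_policies(self):
        rows = self._rows(["A-GU", "AAGU"])
        assert count_variable_positions(rows, gap_policy="ignore-gaps")[0] == 0
        assert count_variable_positions(rows, gap_policy="gaps-as-state")[0] == 1

    def test_subset(self):
        rows = self._rows(["ACGU", "ACGA", "GCGU"])
        n, pos = count_variable_positions(rows, taxa=["r0", "r1"])
        assert (n, pos) == (1, [4])

    def test_unknown_taxon(self):
        with pytest.raises(StructureError, match="unknown taxon"):
            count_variable_positions(self._rows(["ACGU"]), taxa=["zz"])

    def test_matches_naive_column_scan(self):
        rng = np.random.default_rng(5)
        chars = np.array(list("ACGU-"))
        mat = chars[rng.integers(0, 5, size=(6, 120))]
        rows = self._rows(["".join(r) for r in mat])
        n, pos = count_variable_positions(rows)
        # oracle: naive per-column scan
        expected = [
            c + 1
            for c in range(120)
            if len({mat[r, c] for r in range(6)} - {"-"}) >= 2
        ]
        assert pos == expected and n == len(expected)


class TestInsertionBlocks:
    def _rows(self, seqs):
        return [SequenceRecord(id=f"r{i}", seq=s) for i, s in enumerate(seqs)]

    def test_no_gaps_no_blocks(self):
        rows = self._rows(["ACGU" * 30] * 4)
        assert detect_insertion_blocks(rows, ["r0"], min_length=10) == []

    def test_single_block_with_carriers(self):
        core = "ACGU" * 10
        block = "GGGG" * 30  # 120 columns
        rows = self._rows(
            [
                core[:20] + block + core[20:],
                core[:20] + block + core[20:],
                core[:20] + "-" * 120 + core[20:],
                core[:20] + "-" * 120 + core[20:],
            ]
        )
        blocks = detect_insertion_blocks(rows, ["r0", "r1"], min_length=50)
        assert len(blocks) == 1
        assert blocks[0].start == 21
        assert blocks[0].length == 120
        assert blocks[0].carriers == ("r0", "r1")

    def test_below_threshold_ignored(self):
        core = "ACGU" * 5
        rows = self._rows(
            [core[:10] + "G" * 10 + core[10:], core[:10] + "-" * 10 + core[10:]]
        )
        assert detect_insertion_blocks(rows, ["r0"], min_length=50) == []
        assert len(detect_insertion_blocks(rows, ["r0"], min_length=10)) == 1

    def test_carriers_must_be_proper_subset(self):
        rows = self._rows(["ACGU", "ACGU"])
        with pytest.raises(StructureError, match="proper subset"):
            detect_insertion_blocks(rows, ["r0", "r1"])
        with pytest.raises(StructureError, match="proper subset"):
            detect_insertion_blocks(rows, [])
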