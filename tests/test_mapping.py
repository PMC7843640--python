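"""Alignment optimality, identity, common numbering and recovery checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import enumerate_alignment_score
from thermofluct.core import SequenceRecord
from thermofluct.mapping import (
    AlignParams,
    align_many,
    align_pair,
    build_map,
    check_structure_sequence,
    percent_identity,
    _score_table,
)
from thermofluct.synthetic import make_homolog_set, make_reference_structure

AA = "ARNDCQEGHILKMFPSTWYV"


def _rec(name, seq):
    return SequenceRecord(name, seq)


class TestAlignPair:
    def test_identical_sequences_align_gap_free(self):
        aln = align_pair(_rec("a", "MKTAYIAK"), _rec("b", "MKTAYIAK"))
        assert aln.rows == ["MKTAYIAK", "MKTAYIAK"]
        assert percent_identity(aln, "a", "b") == 100.0

    def test_single_deletion_places_one_gap(self):
        aln = align_pair(_rec("a", "ACDEFG"), _rec("b", "ACEFG"))
        assert aln.rows == ["ACDEFG", "AC-EFG"]

    def test_degapping_reproduces_inputs(self):
        a, b = _rec("a", "MKWVTFISLLLF"), _rec("b", "MKWTFLLLF")
        aln = align_pair(a, b)
        assert aln.degapped("a") == a.sequence
        assert aln.degapped("b") == b.sequence

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            SequenceRecord("x", "")

    @pytest.mark.parametrize("seed", range(50))
    def test_score_optimal_vs_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list(AA), size=rng.integers(1, 7)))
        b = "".join(rng.choice(list(AA), size=rng.integers(1, 7)))
        params = AlignParams()
        aln = align_pair(_rec("a", a), _rec("b", b), params)
        oracle = enumerate_alignment_score(
            a, b, _score_table(params.matrix), params.gap_open, params.gap_extend
        )
        assert aln.score == pytest.approx(oracle, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_score_matches_biopython_aligner(self, seed):
        from Bio import Align
        from Bio.Align import substitution_matrices

        rng = np.random.default_rng(100 + seed)
        a = "".join(rng.choice(list(AA), size=rng.integers(10, 40)))
        b = "".join(rng.choice(list(AA), size=rng.integers(10, 40)))
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -1.0
        ours = align_pair(_rec("a", a), _rec("b", b)).score
        assert ours == pytest.approx(aligner.score(a, b), abs=1e-9)


class TestAlignMany:
    def test_identical_sequences_gap_free(self):
        seqs = [_rec(i, "MKTAYIAKQR") for i in "abc"]
        aln = align_many(seqs)
        assert aln.rows == ["MKTAYIAKQR"] * 3

    def test_recovers_generator_ground_truth(self):
        base = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEK"
        variants, maps = make_homolog_set(base, 2, 0.15, 0.02, seed=5)
        records = [_rec("base", base), *variants]
        amap = build_map(align_many(records))
        total = correct = 0
        for variant, truth in zip(variants, maps):
            for base_pos, var_pos in truth.items():
                if var_pos is None:
                    continue
                total += 1
                if amap.column_for("base", base_pos) == amap.column_for(
                    variant.id, var_pos
                ):
                    correct += 1
        assert correct / total >= 0.95

    def test_column_set_invariant_to_input_order(self):
        base = "MKTAYIAKQRQISFVKSHFSRQLEE"
        variants, _ = make_homolog_set(base, 2, 0.2, 0.02, seed=6)
        records = [_rec("base", base), *variants]
        aln1 = align_many(records)
        aln2 = align_many(records[::-1])
        cols1 = {tuple(sorted((sid, row[c]) for sid, row in zip(aln1.ids, aln1.rows)))
                 for c in range(aln1.n_columns)}
        cols2 = {tuple(sorted((sid, row[c]) for sid, row in zip(aln2.ids, aln2.rows)))
                 for c in range(aln2.n_columns)}
        assert cols1 == cols2

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            align_many([_rec("a", "MKT")])


class TestPercentIdentity:
    def test_direct_count(self):
        aln = align_pair(_rec("a", "AAAA"), _rec("b", "AAAT"))
        assert aln.rows == ["AAAA", "AAAT"]
        assert percent_identity(aln, "a", "b") == 75.0

    def test_unknown_id_errors(self):
        aln = align_pair(_rec("a", "AAAA"), _rec("b", "AAAT"))
        with pytest.raises(KeyError):
            percent_identity(aln, "a", "zzz")

    def test_substitution_rate_sets_expected_identity(self):
        base = "".join(
            np.random.default_rng(7).choice(list("ARNDCQEHILKMFPSTWYV"), size=400)
        )
        variants, _ = make_homolog_set(base, 1, 0.2, 0.0, seed=8)
        aln = align_pair(_rec("base", base), variants[0])
        pid = percent_identity(aln, "base", variants[0].id)
        se = 100 * np.sqrt(0.2 * 0.8 / 400)
        assert abs(pid - 80.0) <= 3 * se


class TestBuildMap:
    def test_gap_free_alignment_gives_identity_mapping(self):
        amap = build_map(align_many([_rec(i, "MKTAYIAKQR") for i in "abc"]))
        for sid in "abc":
            assert amap.to_column[sid] == {i: i for i in range(1, 11)}

    def test_deletion_shifts_columns(self):
        aln = align_pair(_rec("a", "ACDEFG"), _rec("b", "ACEFG"))
        amap = build_map(aln)
        assert amap.column_for("a", 4) == 4  # E sits after the gap column
        assert amap.column_for("b", 3) == 4  # b's E maps to the same column
        assert amap.gap_columns["b"] == frozenset({3})

    def test_round_trip_identity(self):
        base = "MKTAYIAKQRQISFVKSHFSR"
        variants, _ = make_homolog_set(base, 2, 0.2, 0.05, seed=9)
        records = [_rec("base", base), *variants]
        amap = build_map(align_many(records))
        for rec in records:
            for residue in range(1, len(rec.sequence) + 1):
                col = amap.column_for(rec.id, residue)
                assert amap.residue_for(rec.id, col) == residue


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    a=st.text(alphabet=AA, min_size=1, max_size=6),
    b=st.text(alphabet=AA, min_size=1, max_size=6),
)
def test_alignment_score_optimality_property(a, b):
    """DP score equals the exhaustive-enumeration optimum on short pairs."""
    params = AlignParams()
    aln = align_pair(_rec("a", a), _rec("b", b), params)
    oracle = enumerate_alignment_score(
        a, b, _score_table(params.matrix), params.gap_open, params.gap_extend
    )
    assert aln.score == pytest.approx(oracle, abs=1e-9)
    assert aln.degapped("a") == a and aln.degapped("b") == b


def test_structure_sequence_consistency_check():
    structure = make_reference_structure(12, seed=10)
    good = SequenceRecord("s", structure.sequence())
    check_structure_sequence(structure, good)
    bad_seq = ("A" if good.sequence[0] != "A" else "C") + good.sequence[1:]
    with pytest.raises(ValueError, match="does not match"):
        check_structure_sequence(structure, SequenceRecord("s", bad_seq))
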