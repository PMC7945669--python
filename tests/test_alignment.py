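"""Length filtering, pairwise/center-star alignment, cropping, cleaning."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import enumeration_alignment_score
from mtharvest.alignment import (
    Alignment,
    LengthSummary,
    align_sequences,
    crop_to_overlap,
    drop_short_sequences,
    import_external_alignment,
    pairwise_align,
    remove_ambiguous_columns,
    summarise_lengths,
    write_alignment_fasta,
)
from mtharvest.core import AccessionRecord, RecordSet

BASES = "ACGT"


def _rs(lengths: dict[str, int]) -> RecordSet:
    return RecordSet(
        records=[
            AccessionRecord(accession_id=k, organism_raw="X y", sequence="A" * n)
            for k, n in lengths.items()
        ]
    )


class TestDropShortSequences:
    def test_boundary_is_strict(self):
        rs = _rs({"A.1": 150, "B.1": 250, "C.1": 200})
        out = drop_short_sequences(rs, 200)
        assert out.accession_ids() == ["B.1", "C.1"]

    def test_minbp_zero_is_identity(self):
        rs = _rs({"A.1": 1, "B.1": 5})
        assert drop_short_sequences(rs, 0).accession_ids() == ["A.1", "B.1"]

    def test_all_longer_nothing_dropped(self):
        rs = _rs({f"S{i}.1": 300 + i for i in range(5)})
        assert len(drop_short_sequences(rs, 200)) == 5


class TestPairwiseAlign:
    def test_single_gap_example(self):
        a, b, score = pairwise_align("ACGTACGT", "ACGACGT")
        assert a == "ACGTACGT"
        assert b == "ACG-ACGT"
        assert score == enumeration_alignment_score("ACGTACGT", "ACGACGT")

    def test_identical_sequences_gapless(self):
        a, b, score = pairwise_align("ACGTACGT", "ACGTACGT")
        assert a == b == "ACGTACGT"
        assert score == 8

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.text(alphabet=BASES, min_size=1, max_size=6),
        st.text(alphabet=BASES, min_size=1, max_size=6),
    )
    def test_dp_score_matches_enumeration(self, a, b):
        _, _, score = pairwise_align(a, b)
        assert score == enumeration_alignment_score(a, b)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.text(alphabet=BASES, min_size=1, max_size=8),
        st.text(alphabet=BASES, min_size=1, max_size=8),
    )
    def test_alignment_strings_degap_to_inputs(self, a, b):
        ga, gb, _ = pairwise_align(a, b)
        assert len(ga) == len(gb)
        assert ga.replace("-", "") == a
        assert gb.replace("-", "") == b


class TestAlignSequences:
    def test_identical_inputs_gap_free(self):
        seqs = {"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGT"}
        aln = align_sequences(seqs)
        assert aln.matrix == ["ACGTACGT"] * 3

    def test_mutated_descendants_roundtrip(self, rng):
        ancestor = "".join(rng.choice(list(BASES), size=30))
        seqs = {}
        for i in range(5):
            s = list(ancestor)
            for p in rng.choice(30, size=3, replace=False):
                s[p] = BASES[(BASES.index(s[p]) + 1) % 4]
            seqs[f"d{i}"] = "".join(s)
        aln = align_sequences(seqs)
        for sid, orig in seqs.items():
            assert aln.degapped(sid) == orig

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            align_sequences({"a": "ACGT"})

    def test_non_iupac_characters_named(self):
        with pytest.raises(ValueError, match="bad1"):
            align_sequences({"bad1": "ACGTZ", "ok": "ACGT"})


class TestCropToOverlap:
    def test_window_from_coverage(self):
        aln = Alignment(
            seq_ids=["a", "b", "c"],
            matrix=["AAAAAAAAAA", "--AAAAAAAA", "AAAAAAAA--"],
        )
        cropped, summary = crop_to_overlap(aln)
        assert cropped.ncol == 6
        assert summary.overlap_length == 6
        assert summary.bp_lost == {"a": 4, "b": 2, "c": 2}

    def test_full_length_rows_unchanged(self):
        aln = Alignment(seq_ids=["a", "b"], matrix=["ACGT", "ACGA"])
        cropped, summary = crop_to_overlap(aln)
        assert cropped.matrix == aln.matrix
        assert summary.bp_lost == {"a": 0, "b": 0}

    def test_idempotent(self, rng):
        ancestor = "".join(rng.choice(list(BASES), size=120))
        seqs = {
            f"s{i}": ancestor[int(rng.integers(0, 15)) : 120 - int(rng.integers(0, 15))]
            for i in range(6)
        }
        aln = align_sequences(seqs)
        once, _ = crop_to_overlap(aln)
        twice, _ = crop_to_overlap(once)
        assert once.matrix == twice.matrix

    def test_heavy_loss_flagged(self, rng):
        ancestor = "".join(rng.choice(list(BASES), size=1000))
        seqs = {f"long{i}": ancestor for i in range(5)}
        seqs["short"] = ancestor[275:725]  # 450 bp
        aln = align_sequences(seqs)
        cropped, summary = crop_to_overlap(aln)
        assert cropped.ncol == 450
        assert summary.heavily_trimmed == sorted(f"long{i}" for i in range(5))
        assert all(summary.bp_lost[f"long{i}"] == 550 for i in range(5))

    def test_disjoint_sequences_rejected(self):
        aln = Alignment(seq_ids=["a", "b"], matrix=["AAAA----", "----TTTT"])
        with pytest.raises(ValueError, match="overlap"):
            crop_to_overlap(aln)

    def test_final_ncol_bounded_by_input_lengths(self, rng):
        ancestor = "".join(rng.choice(list(BASES), size=200))
        seqs = {
            f"s{i}": ancestor[int(rng.integers(0, 30)) : 200 - int(rng.integers(0, 30))]
            for i in range(8)
        }
        aln = align_sequences(seqs)
        cropped, _ = crop_to_overlap(aln)
        cleaned = remove_ambiguous_columns(cropped)
        assert cleaned.ncol <= min(len(s) for s in seqs.values())


class TestRemoveAmbiguousColumns:
    def test_poisoned_columns_removed_exactly(self, rng):
        nrow, ncol, k = 4, 30, 5
        matrix = [
            list("".join(rng.choice(list(BASES), size=ncol))) for _ in range(nrow)
        ]
        poison_cols = sorted(int(c) for c in rng.choice(ncol, size=k, replace=False))
        for c in poison_cols:
            row = int(rng.integers(nrow))
            matrix[row][c] = str(rng.choice(["N", "?", "-", "R"]))
        aln = Alignment(
            seq_ids=[f"s{i}" for i in range(nrow)],
            matrix=["".join(r) for r in matrix],
        )
        cleaned = remove_ambiguous_columns(aln)
        assert cleaned.ncol == ncol - k
        assert cleaned.n_ambiguous_removed == k
        assert cleaned.is_clean()

    def test_clean_alignment_is_identity(self):
        aln = Alignment(seq_ids=["a", "b"], matrix=["ACGT", "ACGA"])
        assert remove_ambiguous_columns(aln).matrix == aln.matrix

    def test_everything_ambiguous_rejected(self):
        aln = Alignment(seq_ids=["a", "b"], matrix=["NN", "AC"])
        with pytest.raises(ValueError, match="no columns remain"):
            remove_ambiguous_columns(aln)


class TestLengthSummary:
    def test_single_sequence(self):
        s = summarise_lengths({"a": 700}, 700)
        table = s.histogram_table()
        assert table["count"].sum() == 1
        assert s.overlap_length == 700

    def test_overlap_bounded_by_shortest(self):
        with pytest.raises(ValueError, match="exceeds"):
            LengthSummary(original_lengths={"a": 1000, "b": 450}, overlap_length=500)

    def test_overlap_equals_clean_ncol_plus_removed(self, rng):
        ancestor = list("".join(rng.choice(list(BASES), size=90)))
        ancestor[40] = "N"  # one ambiguous site shared by everyone
        seqs = {
            f"s{i}": "".join(ancestor[int(rng.integers(0, 10)) : 90 - int(rng.integers(0, 10))])
            for i in range(5)
        }
        aln = align_sequences(seqs)
        cropped, summary = crop_to_overlap(aln)
        cleaned = remove_ambiguous_columns(cropped)
        assert summary.overlap_length == cleaned.ncol + cleaned.n_ambiguous_removed


class TestFastaRoundTrip:
    def test_write_then_import(self, tmp_path, rng):
        aln = Alignment(seq_ids=["a", "b"], matrix=["ACGT-CGT", "ACGTACG-"])
        path = tmp_path / "aln.fasta"
        write_alignment_fasta(aln, path)
        back = import_external_alignment(path)
        assert back.seq_ids == aln.seq_ids
        assert back.matrix == aln.matrix
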