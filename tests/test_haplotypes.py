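"""Haplotype collapse, study flags, magnification, MST network, outliers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import (
    brute_force_flagged_studies,
    brute_force_mst_weight,
    make_haplotype_table,
    random_sequences,
)
from mtharvest.alignment import Alignment
from mtharvest.core import AccessionRecord, RecordSet
from mtharvest.haplotypes import (
    MagnifyTable,
    build_haplotype_network,
    clade_size_summary,
    collapse_haplotypes,
    drop_outliers,
    flag_unique_only_studies,
    hamming,
    magnify_to_sampled_freq,
)


def _aln(rows: dict[str, str]) -> Alignment:
    return Alignment(seq_ids=list(rows), matrix=list(rows.values()))


def _rs(studies: dict[str, str]) -> RecordSet:
    return RecordSet(
        records=[
            AccessionRecord(
                accession_id=a, organism_raw="X y", sequence="A", study_id=s
            )
            for a, s in studies.items()
        ]
    )


class TestCollapse:
    def test_identical_rows_merge(self):
        ht = collapse_haplotypes(_aln({"a": "AAA", "b": "AAA", "c": "AAT"}))
        freqs = sorted(h.frequency for h in ht.rows)
        assert freqs == [1, 2]
        assert ht.total_samples == 3

    def test_all_distinct(self):
        ht = collapse_haplotypes(_aln({"a": "AAA", "b": "AAT", "c": "ATT"}))
        assert ht.n_haplotypes == 3
        assert all(h.frequency == 1 for h in ht.rows)

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            collapse_haplotypes(_bad_aln())

    def test_study_ids_unioned(self):
        rs = _rs({"a": "s1", "b": "s2", "c": "s1"})
        ht = collapse_haplotypes(_aln({"a": "AAA", "b": "AAA", "c": "AAT"}), rs)
        big = ht.find_by_accession("a")
        assert big.study_ids == {"s1", "s2"}


def _bad_aln():
    aln = Alignment(seq_ids=["a", "b"], matrix=["AA", "AA"])
    aln.matrix = ["AA", "AAA"]  # corrupt after validation
    return aln


class TestFlagUniqueOnlyStudies:
    def test_worked_example(self):
        rs = _rs({"a": "A", "b": "A", "c": "A", "d": "B", "e": "B"})
        aln = _aln({"a": "AAA", "b": "AAA", "c": "AAT", "d": "ATT", "e": "TTT"})
        ht = collapse_haplotypes(aln, rs)
        assert flag_unique_only_studies(ht) == ["B"]

    def test_every_study_with_duplicates_unflagged(self):
        rs = _rs({"a": "A", "b": "A", "c": "B", "d": "B"})
        aln = _aln({"a": "AAA", "b": "AAA", "c": "AAT", "d": "AAT"})
        ht = collapse_haplotypes(aln, rs)
        assert flag_unique_only_studies(ht) == []

    def test_matches_brute_force_on_random_tables(self, rng):
        for trial in range(25):
            n_hap = int(rng.integers(2, 6))
            seqs = random_sequences(rng, n_hap, 12)
            n = int(rng.integers(n_hap, 15))
            assignment = list(range(n_hap)) + [
                int(rng.integers(n_hap)) for _ in range(n - n_hap)
            ]
            studies = {}
            rows = {}
            for i, h in enumerate(assignment):
                studies[f"a{i}.1"] = f"S{int(rng.integers(3))}"
                rows[f"a{i}.1"] = seqs[h]
            ht = collapse_haplotypes(_aln(rows), _rs(studies))
            assert set(flag_unique_only_studies(ht)) == brute_force_flagged_studies(ht)


class TestMagnify:
    def test_purple_sandpiper_style_magnification(self):
        ht = make_haplotype_table(["AAA", "AAT"], [1, 3])
        acc = ht.rows[0].member_accessions[0]
        before = ht.total_samples
        ht = magnify_to_sampled_freq(ht, MagnifyTable(counts={acc: 50}))
        assert ht.rows[0].frequency == 50
        assert ht.total_samples == before + 49

    def test_identity_when_equal(self):
        ht = make_haplotype_table(["AAA"], [1])
        acc = ht.rows[0].member_accessions[0]
        ht = magnify_to_sampled_freq(ht, MagnifyTable(counts={acc: 1}))
        assert ht.total_samples == 1

    def test_absent_accession_named_in_error(self):
        ht = make_haplotype_table(["AAA"], [1])
        with pytest.raises(KeyError, match="GHOST.1"):
            magnify_to_sampled_freq(ht, MagnifyTable(counts={"GHOST.1": 5}))

    def test_lowering_contribution_rejected(self):
        ht = make_haplotype_table(["AAA"], [1])
        acc = ht.rows[0].member_accessions[0]
        magnify_to_sampled_freq(ht, MagnifyTable(counts={acc: 4}))
        with pytest.raises(ValueError, match="below"):
            magnify_to_sampled_freq(ht, MagnifyTable(counts={acc: 2}))

    def test_total_increase_equals_sum_of_deltas(self, rng):
        ht = make_haplotype_table(["AAAA", "AATA", "TTTT"], [2, 3, 1])
        accs = [h.member_accessions[0] for h in ht.rows]
        targets = {a: int(rng.integers(1, 10)) for a in accs}
        targets = {a: max(1, t) for a, t in targets.items()}
        delta = sum(max(0, t - 1) for t in targets.values())
        targets = {a: max(t, 1) for a, t in targets.items()}
        before = ht.total_samples
        ht = magnify_to_sampled_freq(
            ht, MagnifyTable(counts={a: max(t, 1) for a, t in targets.items()})
        )
        assert ht.total_samples == before + delta


class TestNetwork:
    def test_two_haplotypes_distance_one(self):
        ht = make_haplotype_table(["AAA", "AAT"], [2, 1])
        net = build_haplotype_network(ht)
        assert net.edges == [("H1", "H2", 1)]
        assert net.min_dist == {"H1": 1, "H2": 1}

    def test_single_haplotype(self):
        ht = make_haplotype_table(["AAA"], [3])
        net = build_haplotype_network(ht)
        assert net.edges == []
        assert net.min_dist == {}

    def test_star_topology(self):
        center = "AAAAAAAA"
        leaves = ["TAAAAAAA", "ACAAAAAA", "AAGAAAAA", "AAATAAAA"]
        ht = make_haplotype_table([center] + leaves, [5, 1, 1, 1, 1])
        net = build_haplotype_network(ht)
        assert len(net.edges) == 4
        assert all("H1" in (a, b) for a, b, _ in net.edges)
        assert all(w == 1 for _, _, w in net.edges)

    def test_mst_weight_matches_brute_force(self, rng):
        for trial in range(60):
            n = int(rng.integers(2, 7))
            seqs = random_sequences(rng, n, 10)
            ht = make_haplotype_table(seqs, [1] * n)
            net = build_haplotype_network(ht)
            assert len(net.edges) == n - 1
            expected = brute_force_mst_weight(
                n, lambda i, j: hamming(seqs[i], seqs[j])
            )
            assert net.total_weight == expected

    def test_min_dist_from_full_matrix_not_tree(self):
        # chain A--B--C where A and C are also close: min_dist(C) uses the
        # full matrix even if the tree connects C through B
        seqs = ["AAAAAA", "AATAAA", "AATTAA"]
        ht = make_haplotype_table(seqs, [1, 1, 1])
        net = build_haplotype_network(ht)
        assert net.min_dist["H1"] == 1
        assert net.min_dist["H3"] == 1

    def test_clade_size_summary_totals_samples(self):
        ht = make_haplotype_table(["AAAAAA", "AATAAA", "TTTTTT"], [4, 2, 1])
        net = build_haplotype_network(ht)
        sizes = clade_size_summary(net, split_bp=3)
        assert sorted(sizes, reverse=True) == [6, 1]


class TestHammingMetric:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_metric_axioms(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = ("".join(rng.choice(list("ACGT"), size=15)) for _ in range(3))
        assert hamming(a, a) == 0
        assert hamming(a, b) == hamming(b, a)
        assert hamming(a, c) <= hamming(a, b) + hamming(b, c)
        assert (hamming(a, b) == 0) == (a == b)


class TestDropOutliers:
    def _table(self, min_dist: int, freq: int = 1):
        base = "A" * 40
        near = "A" * 39 + "T"  # 1 bp from base, far from the outlier
        far = "T" * min_dist + "A" * (40 - min_dist)
        return make_haplotype_table([base, near, far], [5, 3, freq])

    def test_divergent_singleton_removed(self, tmp_path):
        ht = self._table(31)
        out, removed = drop_outliers(ht, threshold=30, fasta_path=tmp_path / "o.fasta")
        assert removed == ["H3"]
        assert out.n_haplotypes == 2
        text = (tmp_path / "o.fasta").read_text()
        assert "T" * 31 not in text

    def test_boundary_is_strict(self):
        ht = self._table(30)
        out, removed = drop_outliers(ht, threshold=30)
        assert removed == []
        assert out.n_haplotypes == 3

    def test_frequency_two_retained_however_divergent(self):
        ht = self._table(35, freq=2)
        out, removed = drop_outliers(ht, threshold=30)
        assert removed == []

    def test_idempotent(self):
        ht = self._table(31)
        once, removed1 = drop_outliers(ht, threshold=30)
        twice, removed2 = drop_outliers(once, threshold=30)
        assert removed2 == []
        assert [h.haplotype_id for h in twice.rows] == [
            h.haplotype_id for h in once.rows
        ]

    def test_multiple_outliers_removed_most_divergent_first(self):
        base = "A" * 80
        far1 = "A" * 45 + "T" * 35  # 35 bp from base, 70 from far2
        far2 = "T" * 35 + "A" * 45
        ht = make_haplotype_table([base, far1, far2], [5, 1, 1])
        out, removed = drop_outliers(ht, threshold=30)
        assert set(removed) == {"H2", "H3"}
        assert out.n_haplotypes == 1

    def test_divergent_pair_of_singletons_protects_both(self):
        # two singletons far from the bulk but close to each other are not
        # "separated from all others" and must survive
        base = "A" * 80
        far1 = "T" * 35 + "A" * 45
        far2 = "T" * 34 + "C" + "A" * 45  # 1 bp from far1
        ht = make_haplotype_table([base, far1, far2], [5, 1, 1])
        _, removed = drop_outliers(ht, threshold=30)
        assert removed == []
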