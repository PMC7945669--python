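"""GenBank parsing, feature scraping and RefSeq deduplication."""

from __future__ import annotations

import textwrap

import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from mtharvest import fixtures, records_io


def _write_gb(tmp_path, records, name="test.gb"):
    path = tmp_path / name
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")
    return path


def _simple_record(accession, seq="ACGTACGTACGT", organism="Motacilla alba", features=()):
    rec = SeqRecord(
        Seq(seq), id=accession, name=accession.split(".")[0], description="test"
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["organism"] = organism
    rec.annotations["topology"] = "linear"
    for ftype, quals in features:
        rec.features.append(
            SeqFeature(SimpleLocation(0, len(seq), 1), type=ftype, qualifiers=quals)
        )
    return rec


class TestLoadAccessionList:
    def test_deduplicates_preserving_order(self, tmp_path):
        path = tmp_path / "acc.csv"
        path.write_text("accession\nAY703261.1\nAY703261.1\nNC_025609.1\n")
        assert records_io.load_accession_list(path) == ["AY703261.1", "NC_025609.1"]

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        path = tmp_path / "acc.csv"
        path.write_text("")
        with caplog.at_level("WARNING"):
            assert records_io.load_accession_list(path) == []
        assert "no accessions" in caplog.text

    def test_generated_list_count_matches_request(self, tmp_path):
        spec = fixtures.FixtureSpec(
            seed=3, studies=(fixtures.StudySpec(n_samples=25),)
        )
        out = fixtures.generate_records(spec, tmp_path)
        accs = records_io.load_accession_list(out.accession_list_path)
        assert len(accs) == 25

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(OSError):
            records_io.load_accession_list(tmp_path / "nope.csv")


class TestParseGenbank:
    def test_seq_length_computed_from_origin(self, tmp_path):
        path = _write_gb(tmp_path, [_simple_record("AY000001.1", "ACGT" * 5)])
        rs = records_io.parse_genbank_records(path)
        assert len(rs) == 1
        assert rs.records[0].seq_length == 20
        assert rs.records[0].sequence == "ACGT" * 5
        assert rs.records[0].organism_raw == "Motacilla alba"

    def test_record_without_origin_skipped_with_warning(self, tmp_path, caplog):
        # handcrafted entry with no ORIGIN letters
        no_origin = textwrap.dedent(
            """\
            LOCUS       AY000002                  12 bp    DNA     linear   VRT 01-JAN-1980
            DEFINITION  test.
            ACCESSION   AY000002
            VERSION     AY000002.1
            FEATURES             Location/Qualifiers
                 source          1..12
                                 /organism="Motacilla alba"
            ORIGIN
            //
            """
        )
        path = tmp_path / "mixed.gb"
        with open(path, "w") as fh:
            SeqIO.write([_simple_record("AY000001.1")], fh, "genbank")
            fh.write(no_origin)
        with caplog.at_level("WARNING"):
            rs = records_io.parse_genbank_records(path)
        assert rs.accession_ids() == ["AY000001.1"]
        assert "no ORIGIN" in caplog.text
        assert rs.provenance_log[0][1:] == (2, 1)

    def test_refseq_flag_from_underscore(self, tmp_path):
        spec = fixtures.FixtureSpec(
            seed=5,
            studies=(fixtures.StudySpec(n_samples=17),),
            n_refseq_duplicates=3,
        )
        out = fixtures.generate_records(spec, tmp_path)
        rs = records_io.parse_genbank_records(out.genbank_path)
        assert len(rs) == 20
        assert sum(r.is_refseq for r in rs) == 3

    def test_study_id_from_reference_hash(self, small_fixture):
        _, out = small_fixture
        rs = records_io.parse_genbank_records(out.genbank_path)
        ledger = out.ledgers[0]
        # records from the same study share a study id; different studies differ
        ids_by_study = {
            label: {rs.get(a).study_id for a in accs}
            for label, accs in ledger.study_accessions.items()
        }
        for ids in ids_by_study.values():
            assert len(ids) == 1
        all_ids = [next(iter(v)) for v in ids_by_study.values()]
        assert len(set(all_ids)) == len(all_ids)


class TestScrapeFeatureItems:
    def test_gene_and_cds_tags_yield_two_items(self, tmp_path):
        rec = _simple_record(
            "AY000001.1",
            features=[
                ("gene", {"gene": ["ND2"]}),
                ("CDS", {"gene": ["ND2"], "product": ["NADH dehydrogenase subunit 2"]}),
            ],
        )
        path = _write_gb(tmp_path, [rec])
        rs = records_io.parse_genbank_records(path)
        items = records_io.scrape_feature_items(rs)
        assert len(items) == 2
        assert {i.feature_kind for i in items} == {"gene", "CDS"}
        assert all(i.gene_name_raw == "ND2" for i in items)

    def test_source_only_record_yields_no_items(self, tmp_path):
        rec = _simple_record(
            "AY000001.1", features=[("source", {"organism": ["Motacilla alba"]})]
        )
        rs = records_io.parse_genbank_records(_write_gb(tmp_path, [rec]))
        assert records_io.scrape_feature_items(rs) == []

    def test_item_tally_matches_generator_ledger(self, small_fixture):
        _, out = small_fixture
        rs = records_io.parse_genbank_records(out.genbank_path)
        items = records_io.scrape_feature_items(rs)
        ledger = out.ledgers[0]
        non_refseq = [
            i for i in items if "_" not in i.accession_id
        ]
        assert len(non_refseq) == sum(ledger.item_counts.values())
        per_record = {}
        for i in non_refseq:
            per_record[i.accession_id] = per_record.get(i.accession_id, 0) + 1
        assert per_record == ledger.item_counts


class TestRemoveRefseqDuplicates:
    def test_synthetic_525_set_reduces_to_523(self, tmp_path):
        spec = fixtures.FixtureSpec(
            seed=7,
            studies=(
                fixtures.StudySpec(n_samples=262),
                fixtures.StudySpec(n_samples=261),
            ),
            n_haplotypes=8,
            n_refseq_duplicates=2,
        )
        out = fixtures.generate_records(spec, tmp_path)
        rs = records_io.parse_genbank_records(out.genbank_path)
        assert len(rs) == 525
        deduped = records_io.remove_refseq_duplicates(rs)
        assert len(deduped) == 523
        removed = set(rs.accession_ids()) - set(deduped.accession_ids())
        assert removed == set(out.ledgers[0].refseq_duplicates)

    def test_no_underscore_set_unchanged(self, tmp_path):
        recs = [_simple_record(f"AY00000{i}.1") for i in range(3)]
        rs = records_io.parse_genbank_records(_write_gb(tmp_path, recs))
        assert records_io.remove_refseq_duplicates(rs).accession_ids() == (
            rs.accession_ids()
        )

    def test_lone_refseq_without_original_retained(self, tmp_path):
        rec = _simple_record("NC_000001.1", organism="Picoides tridactylus")
        rs = records_io.parse_genbank_records(_write_gb(tmp_path, [rec]))
        out = records_io.remove_refseq_duplicates(rs)
        assert out.accession_ids() == ["NC_000001.1"]

    def test_sequence_and_organism_fallback_without_declared_source(self, tmp_path):
        original = _simple_record("AY000001.1", seq="ACGT" * 6)
        copy = _simple_record("NC_000001.1", seq="ACGT" * 6)
        rs = records_io.parse_genbank_records(_write_gb(tmp_path, [original, copy]))
        out = records_io.remove_refseq_duplicates(rs)
        assert out.accession_ids() == ["AY000001.1"]

    def test_idempotent(self, small_fixture):
        _, out = small_fixture
        rs = records_io.parse_genbank_records(out.genbank_path)
        once = records_io.remove_refseq_duplicates(rs)
        twice = records_io.remove_refseq_duplicates(once)
        assert once.accession_ids() == twice.accession_ids()
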