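"""Read GenBank flat files and accession lists; scrape features; deduplicate.

Public repositories can return two accessions for the same underlying sample:
the original submission and a curated RefSeq copy.  RefSeq accessions always
contain an underscore, so they are easy to recognise; a RefSeq record is
removed here only when the original it duplicates is itself present in the
set (otherwise removing it would discard the only copy of the data).
"""

from __future__ import annotations

import csv
import hashlib
import io
import re
from pathlib import Path
from typing import Union

from Bio import SeqIO

from .core import AccessionRecord, FeatureItem, RecordSet, logger

PathLike = Union[str, Path]

# Accession-like token (e.g. AY703261.1, NC_025609.1) used to resolve the
# source record a RefSeq entry was derived from.
_ACCESSION_RE = re.compile(r"\b([A-Z]{1,4}_?\d{5,8}(?:\.\d+)?)\b")
_DERIVED_RE = re.compile(
    r"derived\s+from\s+([A-Z]{1,4}_?\d{5,8}(?:\.\d+)?)", re.IGNORECASE
)


def load_accession_list(path: PathLike) -> list[str]:
    """Read a one-column accession list (optional header), deduplicated.

    Returns whitespace-trimmed accession strings in first-seen order.  A row
    whose first cell looks like a header (``accession`` in any case) is
    skipped.  Duplicate accessions are dropped and their count logged.
    """
    path = Path(path)
    seen: set[str] = set()
    out: list[str] = []
    n_dup = 0
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            token = row[0].strip()
            if not token:
                continue
            if token.lower() in {"accession", "accession_id", "accessions"}:
                continue
            if token in seen:
                n_dup += 1
                continue
            seen.add(token)
            out.append(token)
    if n_dup:
        logger.info("load_accession_list: removed %d duplicate accessions", n_dup)
    if not out:
        logger.warning("load_accession_list: %s contained no accessions", path)
    return out


def _study_id(seqrecord) -> str:
    """Publication identifier: hash of the first reference's title+authors."""
    refs = seqrecord.annotations.get("references") or []
    for ref in refs:
        title = (ref.title or "").strip().rstrip(".")
        authors = (ref.authors or "").strip()
        if title or authors:
            digest = hashlib.sha1(f"{title}|{authors}".encode()).hexdigest()[:10]
            return f"study:{digest}"
    return f"unknown:{seqrecord.id}"


def _scrape_record_features(seqrecord, accession_id: str) -> list[FeatureItem]:
    items: list[FeatureItem] = []
    for feat in seqrecord.features:
        quals = feat.qualifiers
        name = ""
        for key in ("gene", "product", "standard_name"):
            if quals.get(key):
                name = str(quals[key][0]).strip()
                break
        if not name:
            continue  # gene-bearing tags only
        kind = feat.type if feat.type in ("source", "gene", "CDS") else (
            "misc" if feat.type.startswith("misc") else "other"
        )
        span = None
        strand = "unknown"
        if feat.location is not None:
            span = (int(feat.location.start) + 1, int(feat.location.end))
            if feat.location.strand == 1:
                strand = "+"
            elif feat.location.strand == -1:
                strand = "-"
        items.append(
            FeatureItem(
                accession_id=accession_id,
                feature_kind=kind,
                gene_name_raw=name,
                span=span,
                strand=strand,
            )
        )
    return items


def _record_sequence(seqrecord) -> str:
    """ORIGIN letters of an entry, or '' when the entry carries none."""
    if seqrecord.seq is None:
        return ""
    try:
        return str(seqrecord.seq).upper()
    except Exception:  # Bio.Seq.UndefinedSequenceError on contigs / no ORIGIN
        return ""


def _parse_genbank_handle(handle, source: str) -> RecordSet:
    rs = RecordSet()
    seen: set[str] = set()
    n_parsed = 0
    try:
        for seqrecord in SeqIO.parse(handle, "genbank"):
            n_parsed += 1
            seq = _record_sequence(seqrecord)
            if not seq:
                logger.warning(
                    "parse_genbank_records: %s has no ORIGIN sequence; skipped",
                    seqrecord.id,
                )
                continue
            accession = seqrecord.id
            if accession in seen:
                logger.warning(
                    "parse_genbank_records: duplicate accession %s; keeping first",
                    accession,
                )
                continue
            seen.add(accession)
            record = AccessionRecord(
                accession_id=accession,
                organism_raw=seqrecord.annotations.get("organism", "").strip(),
                sequence=seq,
                study_id=_study_id(seqrecord),
            )
            record.features = _scrape_record_features(seqrecord, accession)
            # RefSeq provenance for dedup: DBSOURCE or COMMENT cross-reference
            record.refseq_source = _refseq_source(seqrecord)  # type: ignore[attr-defined]
            rs.records.append(record)
    except ValueError as exc:
        raise ValueError(f"malformed GenBank entry in {source}: {exc}") from exc
    rs.log("parse_genbank_records", n_parsed, len(rs.records))
    rs.validate()
    return rs


def parse_genbank_records(path: PathLike) -> RecordSet:
    """Parse a (multi-entry) GenBank flat file into a :class:`RecordSet`.

    The sequence length is computed from the ORIGIN letters, never trusted
    from the LOCUS line.  Entries without sequence data are skipped with a
    warning; a malformed entry raises ``ValueError`` naming the file.
    Duplicate accession ids keep the first occurrence.
    """
    path = Path(path)
    with open(path) as handle:
        return _parse_genbank_handle(handle, str(path))


def _refseq_source(seqrecord) -> str | None:
    """Declared source accession of a RefSeq record, if the entry carries one."""
    if "_" not in seqrecord.id:
        return None
    for field in ("db_source", "comment"):
        text = seqrecord.annotations.get(field) or ""
        if isinstance(text, (list, tuple)):
            text = " ".join(text)
        m = _DERIVED_RE.search(text)
        if m:
            return m.group(1)
        m = _ACCESSION_RE.search(text.replace(seqrecord.id, ""))
        if m and "_" not in m.group(1):
            return m.group(1)
    return None


def scrape_feature_items(rs: RecordSet) -> list[FeatureItem]:
    """Collect every gene-bearing feature item across the set.

    A record annotating the same gene under both a ``gene`` and a ``CDS`` tag
    contributes two items; collapsing that redundancy is deliberately left to
    the gene-standardisation step so the raw tally stays auditable.
    """
    items: list[FeatureItem] = []
    for record in rs:
        items.extend(record.features)
    logger.info(
        "scrape_feature_items: %d items from %d accessions", len(items), len(rs)
    )
    return items


def remove_refseq_duplicates(rs: RecordSet) -> RecordSet:
    """Drop RefSeq records whose original accession is present in the set.

    Resolution order: the record's declared source cross-reference (DBSOURCE
    or COMMENT); failing that, any non-RefSeq record with an identical
    sequence and organism.  A RefSeq record with no present original is
    retained.  Idempotent.
    """
    present = set(rs.accession_ids())
    present_unversioned = {a.split(".")[0] for a in present}
    by_seq_org: dict[tuple[str, str], list[AccessionRecord]] = {}
    for r in rs:
        if not r.is_refseq:
            by_seq_org.setdefault((r.sequence, r.organism_raw), []).append(r)

    kept: list[AccessionRecord] = []
    removed: list[str] = []
    for r in rs:
        if r.is_refseq:
            source = getattr(r, "refseq_source", None)
            if source and (
                source in present or source.split(".")[0] in present_unversioned
            ):
                removed.append(r.accession_id)
                continue
            if source is None and by_seq_org.get((r.sequence, r.organism_raw)):
                removed.append(r.accession_id)
                continue
        kept.append(r)
    if removed:
        logger.info(
            "remove_refseq_duplicates: removed %d RefSeq duplicates: %s",
            len(removed),
            ", ".join(removed),
        )
    return rs.replace_records("remove_refseq_duplicates", kept)


def write_metadata_table(rs: RecordSet, path: PathLike) -> None:
    """Write the record metadata as a delimited table."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["accession_id", "organism", "seq_length", "study_id", "is_refseq"]
        )
        for r in rs:
            writer.writerow(
                [r.accession_id, r.organism_raw, r.seq_length, r.study_id, r.is_refseq]
            )


def write_fasta(rs: RecordSet, path: PathLike) -> None:
    """Write the raw sequences as FASTA keyed by accession id."""
    with open(path, "w") as fh:
        for r in rs:
            fh.write(f">{r.accession_id}\n")
            for i in range(0, len(r.sequence), 70):
                fh.write(r.sequence[i : i + 70] + "\n")


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def parse_genbank_text(text: str) -> RecordSet:
    """Convenience wrapper: parse GenBank flat-file content from a string."""
    return _parse_genbank_handle(io.StringIO(text), "<string>")
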