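"""Core containers shared across the curation pipeline.

An :class:`AccessionRecord` is one repository entry (one accession, one
nucleotide sequence plus its scraped metadata).  A :class:`RecordSet` is an
ordered collection of records together with a provenance log that tracks how
many records every operation consumed and produced, so the final report can
mirror the narrative bookkeeping of a multi-study curation run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

logger = logging.getLogger("mtharvest")

#: Feature kinds retained when scraping GenBank feature tables.
FEATURE_KINDS = ("source", "gene", "CDS", "misc", "other")


@dataclass
class FeatureItem:
    """One scraped feature-tag row ("item") from a GenBank record.

    A single accession routinely yields several items for the same gene
    because depositors annotate it under multiple tags (``gene``, ``CDS``,
    sometimes ``misc_feature``); the redundancy is resolved later by
    :func:`mtharvest.standardise.gene_of_interest`.
    """

    accession_id: str
    feature_kind: str
    gene_name_raw: str
    gene_name_std: str = ""
    span: Optional[tuple[int, int]] = None  # 1-based inclusive
    strand: str = "unknown"  # one of {+, -, unknown}

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            self.feature_kind = "other"
        if self.span is not None:
            start, end = self.span
            if not 1 <= start <= end:
                raise ValueError(
                    f"feature span {self.span} on {self.accession_id} is not "
                    "1-based inclusive with start <= end"
                )


@dataclass
class AccessionRecord:
    """One repository entry: accession, organism, sequence and features."""

    accession_id: str
    organism_raw: str
    sequence: str
    features: list[FeatureItem] = field(default_factory=list)
    study_id: str = ""
    organism_std: str = ""  # set by standardise_spp_names; '' until then
    needs_review: bool = False  # organism name could not be safely normalised

    @property
    def organism(self) -> str:
        """Standardised organism name when available, else the verbatim one."""
        return self.organism_std or self.organism_raw

    @property
    def seq_length(self) -> int:
        return len(self.sequence)

    @property
    def is_refseq(self) -> bool:
        """RefSeq accessions (and only those) carry an underscore."""
        return "_" in self.accession_id


@dataclass
class RecordSet:
    """Ordered accession records plus an append-only provenance log."""

    records: list[AccessionRecord] = field(default_factory=list)
    provenance_log: list[tuple[str, int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AccessionRecord]:
        return iter(self.records)

    def accession_ids(self) -> list[str]:
        return [r.accession_id for r in self.records]

    def get(self, accession_id: str) -> AccessionRecord:
        for r in self.records:
            if r.accession_id == accession_id:
                return r
        raise KeyError(accession_id)

    def log(self, operation: str, before: int, after: int) -> None:
        if self.provenance_log and self.provenance_log[-1][2] != before:
            raise ValueError(
                f"provenance discontinuity at {operation!r}: previous 'after' "
                f"was {self.provenance_log[-1][2]}, new 'before' is {before}"
            )
        self.provenance_log.append((operation, before, after))

    def replace_records(
        self, operation: str, new_records: Iterable[AccessionRecord]
    ) -> "RecordSet":
        """Return a new RecordSet with ``new_records`` and an extended log."""
        new_records = list(new_records)
        out = RecordSet(records=new_records, provenance_log=list(self.provenance_log))
        out.log(operation, len(self.records), len(new_records))
        return out

    def validate(self) -> None:
        """Check the container invariants; raise ValueError on violation."""
        seen: set[str] = set()
        for r in self.records:
            if r.accession_id in seen:
                raise ValueError(f"duplicate accession id {r.accession_id}")
            seen.add(r.accession_id)
            for item in r.features:
                if item.accession_id != r.accession_id:
                    raise ValueError(
                        f"feature item {item.accession_id!r} attached to "
                        f"record {r.accession_id!r}"
                    )
                if item.span is not None and item.span[1] > r.seq_length:
                    raise ValueError(
                        f"feature span {item.span} exceeds sequence length "
                        f"{r.seq_length} on {r.accession_id}"
                    )
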