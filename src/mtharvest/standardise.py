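"""Normalise gene and organism nomenclature; filter to a gene of interest.

Repository metadata is free text: the same gene appears as ``ND2``, ``nad2``
or ``NADH dehydrogenase subunit 2`` depending on the depositor, and organism
fields mix binomials with subspecies trinomials.  These helpers map all of
that onto one nomenclature before any grouping or filtering happens.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from .core import FeatureItem, RecordSet, logger

PathLike = Union[str, Path]

_STRIP_CHARS = set(".,-_'()/ \t")

#: Tokens that mark hybrids or open nomenclature; truncating such names to a
#: binomial could merge distinct taxa, so they are flagged for manual review.
HYBRID_MARKERS = {"x", "sp", "sp.", "cf", "cf.", "aff", "aff."}


def normalise_name(name: str) -> str:
    """Case-fold and strip punctuation/whitespace for nomenclature matching."""
    return "".join(c for c in name.casefold() if c not in _STRIP_CHARS)


class GeneConversionTable:
    """Maps observed gene-name variants to standard mitochondrial names.

    The bundled default covers 18 commonly sequenced mtDNA genes; users
    working on other systems load their own two-column table
    (``standard_name,variant``, header required).
    """

    def __init__(self, rows: list[tuple[str, str]]):
        self._map: dict[str, str] = {}
        self.standard_names: list[str] = []
        for standard, variant in rows:
            standard = standard.strip()
            key = normalise_name(variant)
            if not key:
                continue
            if key in self._map and self._map[key] != standard:
                raise ValueError(
                    f"gene variant {variant!r} maps to both "
                    f"{self._map[key]!r} and {standard!r}"
                )
            self._map[key] = standard
            if standard not in self.standard_names:
                self.standard_names.append(standard)
            # every standard name is a variant of itself
            self._map.setdefault(normalise_name(standard), standard)

    @classmethod
    def from_csv(cls, path: PathLike) -> "GeneConversionTable":
        rows: list[tuple[str, str]] = []
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None:
                raise ValueError(f"empty gene conversion table: {path}")
            for row in reader:
                if len(row) >= 2 and row[0].strip():
                    rows.append((row[0], row[1]))
        return cls(rows)

    @classmethod
    def default(cls) -> "GeneConversionTable":
        with resources.as_file(
            resources.files("mtharvest.data") / "gene_names.csv"
        ) as p:
            return cls.from_csv(p)

    def lookup(self, raw_name: str) -> Optional[str]:
        return self._map.get(normalise_name(raw_name))

    def __contains__(self, gene: str) -> bool:
        return gene in self.standard_names


@dataclass
class SpeciesNameMap:
    """Explicit organism-name overrides plus the trinomial-truncation switch."""

    mapping: dict[str, str] = field(default_factory=dict)
    trinomial_truncation: bool = True

    def __post_init__(self) -> None:
        for observed, canonical in self.mapping.items():
            if len(canonical.split()) != 2:
                raise ValueError(
                    f"canonical name for {observed!r} must be a two-token "
                    f"binomial, got {canonical!r}"
                )

    @classmethod
    def from_csv(cls, path: PathLike, trinomial_truncation: bool = True):
        mapping: dict[str, str] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            next(reader, None)  # header
            for row in reader:
                if len(row) >= 2 and row[0].strip():
                    mapping[row[0].strip()] = row[1].strip()
        return cls(mapping=mapping, trinomial_truncation=trinomial_truncation)


@dataclass
class StandardiseReport:
    """Changes applied by a standardisation pass."""

    changes: dict[str, str] = field(default_factory=dict)  # old -> new
    change_counts: dict[str, int] = field(default_factory=dict)  # old -> n rows
    unmatched: list[str] = field(default_factory=list)
    flagged_for_review: list[str] = field(default_factory=list)

    @property
    def n_changed(self) -> int:
        return sum(self.change_counts.values())


def standardise_gene_names(
    items: list[FeatureItem], table: Optional[GeneConversionTable] = None
) -> tuple[list[FeatureItem], StandardiseReport]:
    """Fill ``gene_name_std`` on every item from the conversion table.

    Unmatched raw names are copied verbatim into ``gene_name_std`` and listed
    in the report so the user can extend the table.  Idempotent; never
    changes the number of items.
    """
    table = table or GeneConversionTable.default()
    report = StandardiseReport()
    unmatched: set[str] = set()
    for item in items:
        std = table.lookup(item.gene_name_raw)
        if std is None:
            std = item.gene_name_raw
            unmatched.add(item.gene_name_raw)
        if std != item.gene_name_std:
            if item.gene_name_raw != std:
                report.changes[item.gene_name_raw] = std
                report.change_counts[item.gene_name_raw] = (
                    report.change_counts.get(item.gene_name_raw, 0) + 1
                )
            item.gene_name_std = std
    report.unmatched = sorted(unmatched)
    if report.unmatched:
        logger.info(
            "standardise_gene_names: %d unmatched names: %s",
            len(report.unmatched),
            ", ".join(report.unmatched),
        )
    return items, report


def _truncatable(organism: str) -> bool:
    tokens = organism.split()
    if len(tokens) < 3:
        return False
    return not any(t.casefold() in HYBRID_MARKERS for t in tokens)


def standardise_spp_names(
    rs: RecordSet, name_map: Optional[SpeciesNameMap] = None
) -> tuple[RecordSet, StandardiseReport]:
    """Collapse subspecies trinomials to species binomials.

    Explicit map entries override the truncation rule.  Names containing
    hybrid or open-nomenclature markers (``x``, ``sp.``, ``cf.``) are left
    untouched and flagged for manual review.  Idempotent.
    """
    name_map = name_map or SpeciesNameMap()
    report = StandardiseReport()
    for record in rs:
        old = record.organism
        if old in name_map.mapping:
            new = name_map.mapping[old]
        elif record.organism_raw in name_map.mapping:
            new = name_map.mapping[record.organism_raw]
        elif name_map.trinomial_truncation and _truncatable(old):
            new = " ".join(old.split()[:2])
        else:
            new = old
            tokens = old.split()
            if len(tokens) >= 3:
                record.needs_review = True
                report.flagged_for_review.append(record.accession_id)
        record.organism_std = new
        if new != old:
            report.changes[old] = new
            report.change_counts[old] = report.change_counts.get(old, 0) + 1
    out = rs.replace_records("standardise_spp_names", rs.records)
    if report.changes:
        logger.info(
            "standardise_spp_names: %d records renamed (%d distinct names)",
            report.n_changed,
            len(report.changes),
        )
    return out, report


def gene_of_interest(
    rs: RecordSet,
    items: list[FeatureItem],
    gene: str,
    drop_other_genes: bool = True,
    require_gene: bool = True,
    table: Optional[GeneConversionTable] = None,
) -> tuple[RecordSet, list[FeatureItem]]:
    """Restrict records/items to one standard gene.

    ``drop_other_genes`` removes items for other genes; ``require_gene``
    removes records with no item for the target gene.  Duplicate items per
    (accession, gene) — e.g. a ``gene`` and a ``CDS`` tag for the same gene —
    collapse to one, preferring the CDS annotation for its span.
    """
    table = table or GeneConversionTable.default()
    if gene not in table:
        raise ValueError(
            f"gene {gene!r} is not a standard name in the conversion table; "
            f"known: {', '.join(table.standard_names)}"
        )

    # collapse duplicates per (accession, standard gene)
    kind_rank = {"CDS": 0, "gene": 1, "misc": 2, "other": 3, "source": 4}
    best: dict[tuple[str, str], FeatureItem] = {}
    order: list[tuple[str, str]] = []
    for item in items:
        key = (item.accession_id, item.gene_name_std or item.gene_name_raw)
        if key not in best:
            best[key] = item
            order.append(key)
        elif kind_rank.get(item.feature_kind, 9) < kind_rank.get(
            best[key].feature_kind, 9
        ):
            best[key] = item
    collapsed = [best[k] for k in order]

    if drop_other_genes:
        kept_items = [i for i in collapsed if i.gene_name_std == gene]
    else:
        kept_items = collapsed

    if require_gene:
        with_gene = {
            i.accession_id for i in collapsed if i.gene_name_std == gene
        }
        kept_records = [r for r in rs if r.accession_id in with_gene]
    else:
        kept_records = list(rs.records)
    kept_ids = {r.accession_id for r in kept_records}
    kept_items = [i for i in kept_items if i.accession_id in kept_ids]

    out = rs.replace_records(f"gene_of_interest[{gene}]", kept_records)
    logger.info(
        "gene_of_interest: %d/%d records retain %s (%d items)",
        len(out),
        len(rs),
        gene,
        len(kept_items),
    )
    return out, kept_items
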