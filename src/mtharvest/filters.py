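"""Final information-content filters on per-species dataset summaries.

A skyline reconstruction from a single mitochondrial gene needs a minimum
amount of signal.  Datasets with too few haplotypes, too few samples or too
short a sequence are unlikely to constrain the demographic model and are
dropped here, with every failing reason reported.  The default thresholds
(6 haplotypes / 20 samples / 600 bp) suit a single-gene avian analysis and
are deliberately user-visible: there is no universally correct value, and
other genes or taxa will warrant different choices.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

from .alignment import Alignment
from .core import logger
from .haplotypes import HaplotypeTable

PathLike = Union[str, Path]


@dataclass(frozen=True)
class SpeciesSummary:
    """One curated dataset: the three quantities the filters act on."""

    species_name: str
    n_haplotypes: int
    seq_length: int
    sample_size: int

    def __post_init__(self) -> None:
        if min(self.n_haplotypes, self.seq_length, self.sample_size) < 0:
            raise ValueError("summary values must be >= 0")
        if self.n_haplotypes > self.sample_size:
            raise ValueError(
                f"{self.species_name}: n_haplotypes ({self.n_haplotypes}) "
                f"exceeds sample_size ({self.sample_size})"
            )


@dataclass(frozen=True)
class FilterThresholds:
    """Drop boundaries; a dataset passes at exactly the threshold value."""

    min_haplotypes: int = 6
    min_samples: int = 20
    min_bp: int = 600

    def __post_init__(self) -> None:
        if min(self.min_haplotypes, self.min_samples, self.min_bp) < 0:
            raise ValueError("thresholds must be >= 0")


def summarise_species(
    species_name: str, ht: HaplotypeTable, aln: Alignment
) -> SpeciesSummary:
    """Table-row summary of a fully processed species dataset."""
    return SpeciesSummary(
        species_name=species_name,
        n_haplotypes=ht.n_haplotypes,
        seq_length=aln.ncol if ht.rows else 0,
        sample_size=ht.total_samples,
    )


def failing_reasons(s: SpeciesSummary, t: FilterThresholds) -> list[str]:
    """All thresholds a summary fails (strictly-below semantics)."""
    reasons = []
    if s.sample_size < t.min_samples:
        reasons.append("sample_size")
    if s.n_haplotypes < t.min_haplotypes:
        reasons.append("n_haplotypes")
    if s.seq_length < t.min_bp:
        reasons.append("seq_length")
    return reasons


def apply_filters(
    summaries: Iterable[SpeciesSummary],
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[SpeciesSummary], list[tuple[SpeciesSummary, list[str]]]]:
    """Split summaries into retained and (dropped, reasons) lists.

    The three predicates are independent, so applying them in any order —
    or, as here, at once — retains the same set.
    """
    retained: list[SpeciesSummary] = []
    dropped: list[tuple[SpeciesSummary, list[str]]] = []
    for s in summaries:
        reasons = failing_reasons(s, thresholds)
        if reasons:
            dropped.append((s, reasons))
        else:
            retained.append(s)
    for s, reasons in dropped:
        logger.info(
            "apply_filters: dropped %s (%s)", s.species_name, ", ".join(reasons)
        )
    return retained, dropped


def drop_low_sample_size(
    summaries: Iterable[SpeciesSummary], min_samples: int = 20
) -> list[SpeciesSummary]:
    return [s for s in summaries if s.sample_size >= min_samples]


def drop_low_haplo_number(
    summaries: Iterable[SpeciesSummary], min_haplotypes: int = 6
) -> list[SpeciesSummary]:
    return [s for s in summaries if s.n_haplotypes >= min_haplotypes]


def drop_low_sequence_length(
    summaries: Iterable[SpeciesSummary], min_bp: int = 600
) -> list[SpeciesSummary]:
    return [s for s in summaries if s.seq_length >= min_bp]


def write_summary_table(
    summaries: Iterable[SpeciesSummary], path: PathLike
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species_name", "n_haplotypes", "seq_length", "sample_size"])
        for s in summaries:
            writer.writerow(
                [s.species_name, s.n_haplotypes, s.seq_length, s.sample_size]
            )


def read_summary_table(path: PathLike) -> list[SpeciesSummary]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                SpeciesSummary(
                    species_name=row["species_name"],
                    n_haplotypes=int(row["n_haplotypes"]),
                    seq_length=int(row["seq_length"]),
                    sample_size=int(row["sample_size"]),
                )
            )
    return out
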