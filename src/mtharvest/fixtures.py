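"""Seeded synthetic GenBank fixtures with ledgered ground truth.

Real multi-study repository data arrives with a predictable set of
pathologies: subspecies trinomials in the organism field, gene names spelled
differently under different feature tags, curated RefSeq copies duplicating
original submissions, studies that sequenced different spans of the gene,
studies that deposited one accession per haplotype instead of one per
individual, and the occasional wildly divergent singleton.  The generator
here emits GenBank flat files exhibiting exactly the requested pathologies —
and, crucially, a :class:`FixtureLedger` recording the ground truth for
every downstream pipeline stage, so end-to-end recovery can be asserted
exactly.

Sequences are built by mutating a random ancestor at recorded positions
inside a core region covered by every study's span, so haplotype identities
and Hamming distances survive overlap cropping by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import Reference, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .beast_io import TraceSeries
from .haplotypes import MagnifyTable

PathLike = Union[str, Path]

_BASES = np.array(list("ACGT"))

#: Raw-name pool for the gene of interest; all standardise to ND2.
ND2_VARIANTS = (
    "ND2",
    "nd2",
    "nad2",
    "NADH2",
    "ND-2",
    "NADH dehydrogenase subunit 2",
    "NADH dehydrogenase subunit II",
)


@dataclass
class StudySpec:
    """One depositing study within a species fixture."""

    n_samples: int
    deposition: str = "all"  # "all" or "unique" (one accession per haplotype)

    def __post_init__(self) -> None:
        if self.deposition not in ("all", "unique"):
            raise ValueError(f"unknown deposition style {self.deposition!r}")
        if self.n_samples < 1:
            raise ValueError("a study needs at least one sample")


@dataclass
class FixtureSpec:
    """Knobs of one synthetic multi-study dataset."""

    seed: int = 0
    species_names: tuple[str, ...] = ("Motacilla synthetica",)
    studies: tuple[StudySpec, ...] = (
        StudySpec(n_samples=10),
        StudySpec(n_samples=8),
    )
    n_haplotypes: int = 4
    gene_length: int = 480
    subspecies_rate: float = 0.2
    gene_variant_pool: tuple[str, ...] = ND2_VARIANTS
    n_refseq_duplicates: int = 0
    n_outliers: int = 0
    outlier_divergence_bp: int = 35
    extra_gene_rate: float = 0.15  # chance of an extra non-target gene item
    max_haplotype_mutations: int = 3

    def __post_init__(self) -> None:
        total = sum(s.n_samples for s in self.studies)
        if self.n_outliers > total:
            raise ValueError("more outliers requested than samples")
        if self.n_outliers and self.outlier_divergence_bp <= 0:
            raise ValueError("outlier divergence must be > 0")
        if self.n_haplotypes < 1:
            raise ValueError("need at least one haplotype")
        needed = (
            self.n_haplotypes * self.max_haplotype_mutations
            + self.n_outliers * self.outlier_divergence_bp
        )
        if needed > self.gene_length // 2:
            raise ValueError(
                "gene_length too short for the requested mutation budget"
            )


@dataclass
class FixtureLedger:
    """Ground truth for one generated dataset (single species)."""

    species: str
    accessions: list[str] = field(default_factory=list)
    # accession -> haplotype index (outliers get indices >= n_haplotypes)
    haplotype_of: dict[str, int] = field(default_factory=dict)
    # accession -> number of individuals the accession represents
    samples_of: dict[str, int] = field(default_factory=dict)
    # per-study bookkeeping: study label -> accessions / style
    study_accessions: dict[str, list[str]] = field(default_factory=dict)
    study_style: dict[str, str] = field(default_factory=dict)
    study_ref_title: dict[str, str] = field(default_factory=dict)
    refseq_duplicates: list[str] = field(default_factory=list)
    outlier_accessions: list[str] = field(default_factory=list)
    # accession -> count of gene-bearing feature tags emitted
    item_counts: dict[str, int] = field(default_factory=dict)
    # expected post-pipeline state
    true_sample_total: int = 0
    true_haplotype_frequencies: list[int] = field(default_factory=list)
    expected_seq_length: int = 0
    expected_flagged_studies: list[str] = field(default_factory=list)

    def to_json(self, path: PathLike) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


@dataclass
class FixtureOutput:
    genbank_path: Path
    fasta_path: Path
    magnify_path: Optional[Path]
    magnify: MagnifyTable
    ledgers: list[FixtureLedger]
    accession_list_path: Path


def _mutate(ancestor: np.ndarray, positions: list[int], rng: np.random.Generator):
    seq = ancestor.copy()
    for p in positions:
        current = seq[p]
        choices = [b for b in "ACGT" if b != current]
        seq[p] = choices[rng.integers(0, 3)]
    return seq


def _make_seqrecord(
    accession: str,
    sequence: str,
    organism: str,
    gene_names: list[str],
    ref_title: str,
    ref_authors: str,
    extra_gene: Optional[str] = None,
    refseq_source: Optional[str] = None,
) -> SeqRecord:
    base = accession.split(".")[0]
    rec = SeqRecord(
        Seq(sequence),
        id=accession,
        name=base,
        description=f"{organism} NADH dehydrogenase subunit 2 (ND2) gene, partial cds",
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["organism"] = organism
    rec.annotations["source"] = f"mitochondrion {organism}"
    rec.annotations["topology"] = "linear"
    rec.annotations["data_file_division"] = "VRT"
    rec.annotations["accessions"] = [base]
    rec.annotations["sequence_version"] = int(accession.split(".")[1])
    ref = Reference()
    ref.title = ref_title
    ref.authors = ref_authors
    ref.journal = "Synthetic J. 1:1-10"
    rec.annotations["references"] = [ref]
    if refseq_source is not None:
        rec.annotations["comment"] = (
            "PROVISIONAL REFSEQ: The reference sequence was derived from "
            f"{refseq_source}."
        )
    n = len(sequence)
    loc = SimpleLocation(0, n, 1)
    rec.features.append(
        SeqFeature(loc, type="source", qualifiers={"organism": [organism]})
    )
    for k, name in enumerate(gene_names):
        ftype = ("gene", "CDS", "misc_feature")[k % 3]
        quals = {"gene": [name]}
        if ftype == "CDS":
            quals["product"] = ["NADH dehydrogenase subunit 2"]
        rec.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    if extra_gene is not None:
        rec.features.append(
            SeqFeature(
                SimpleLocation(0, min(30, n), 1),
                type="gene",
                qualifiers={"gene": [extra_gene]},
            )
        )
    return rec


def generate_records(
    spec: FixtureSpec, out_dir: PathLike, prefix: str = "fixture"
) -> FixtureOutput:
    """Write GenBank + FASTA + accession list + magnify table + ledgers.

    Deterministic for a given spec (same seed twice gives byte-identical
    files).  One ledger per species.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    seqrecords: list[SeqRecord] = []
    ledgers: list[FixtureLedger] = []
    magnify_counts: dict[str, int] = {}
    acc_counter = 100000

    for sp_idx, species in enumerate(spec.species_names):
        ledger = FixtureLedger(species=species)
        L = spec.gene_length
        ancestor = _BASES[rng.integers(0, 4, size=L)]
        core_lo, core_hi = L // 4, (3 * L) // 4  # every span covers the core

        # disjoint mutation positions keep haplotype distances exact
        budget = (
            spec.n_haplotypes * spec.max_haplotype_mutations
            + spec.n_outliers * spec.outlier_divergence_bp
        )
        # Mutated sites stay a few bases clear of every span edge (a variant
        # on a terminal aligned base is ambiguous with a gap+shift path), and
        # outlier substitutions sit on a >= 6 bp grid so they stay isolated
        # point differences — clustered substitutions can genuinely realign
        # as indels, which would blur the ledgered distances.
        usable = np.arange(core_lo + 3, core_hi - 3)
        grid = [int(p) for p in usable[:: 6]]
        need_grid = spec.n_outliers * spec.outlier_divergence_bp
        if need_grid > len(grid):
            raise ValueError(
                "gene_length too short for the requested outlier divergence"
            )
        grid_used = set(grid[:need_grid])
        hap_pool = [int(p) for p in usable if int(p) not in grid_used]
        hap_budget = spec.n_haplotypes * spec.max_haplotype_mutations
        if hap_budget > len(hap_pool):
            raise ValueError(
                "gene_length too short for the requested haplotype diversity"
            )
        pool = list(
            rng.choice(np.array(hap_pool), size=hap_budget, replace=False)
        )
        haplotypes: list[str] = ["".join(ancestor)]
        for _ in range(spec.n_haplotypes - 1):
            n_mut = int(rng.integers(1, spec.max_haplotype_mutations + 1))
            positions = [int(pool.pop()) for _ in range(n_mut)]
            haplotypes.append("".join(_mutate(ancestor, positions, rng)))
        outlier_seqs: list[str] = []
        for k in range(spec.n_outliers):
            lo_k = k * spec.outlier_divergence_bp
            positions = grid[lo_k : lo_k + spec.outlier_divergence_bp]
            outlier_seqs.append("".join(_mutate(ancestor, positions, rng)))

        # per-study spans: contain the core, vary at the flanks; one
        # all-samples study sequences the whole gene and anchors the
        # alignment (its records are the longest, so the center-star center
        # is always a typical haplotype, never the divergent outlier)
        spans = []
        for _ in spec.studies:
            start = int(rng.integers(0, core_lo + 1))
            end = int(rng.integers(core_hi, L + 1))
            spans.append((start, end))
        anchor_idx = next(
            (i for i, st in enumerate(spec.studies) if st.deposition == "all"), 0
        )
        spans[anchor_idx] = (0, L)
        window_lo = max(s for s, _ in spans)
        window_hi = min(e for _, e in spans)
        ledger.expected_seq_length = window_hi - window_lo

        # assign samples to haplotypes (every haplotype sampled at least once)
        total = sum(s.n_samples for s in spec.studies)
        assignment = list(range(spec.n_haplotypes))
        assignment += [
            int(rng.integers(0, spec.n_haplotypes))
            for _ in range(total - spec.n_haplotypes)
        ]
        rng.shuffle(assignment)

        # outliers replace samples in "all"-style studies
        sample_slots: list[tuple[int, int]] = []  # (study index, slot)
        pos = 0
        for st_idx, st in enumerate(spec.studies):
            for slot in range(st.n_samples):
                sample_slots.append((st_idx, pos))
                pos += 1
        anchor_first_slot = min(
            (i for i, (st_idx, _) in enumerate(sample_slots) if st_idx == anchor_idx),
            default=None,
        )
        all_style_slots = [
            i
            for i, (st_idx, _) in enumerate(sample_slots)
            if spec.studies[st_idx].deposition == "all" and st_idx != anchor_idx
        ] or [
            i
            for i, (st_idx, _) in enumerate(sample_slots)
            if spec.studies[st_idx].deposition == "all" and i != anchor_first_slot
        ]
        if spec.n_outliers > len(all_style_slots):
            raise ValueError(
                "not enough samples in all-style studies to host the outliers"
            )
        outlier_slot_ids = [
            all_style_slots[int(i)]
            for i in rng.choice(
                len(all_style_slots), size=spec.n_outliers, replace=False
            )
        ]
        for k, slot_id in enumerate(outlier_slot_ids):
            assignment[sample_slots[slot_id][1]] = spec.n_haplotypes + k
        all_seqs = haplotypes + outlier_seqs

        # emit records study by study
        true_freqs = [0] * len(all_seqs)
        refseq_candidates: list[tuple[str, str, str]] = []  # (acc, seq, organism)
        pos = 0
        for st_idx, st in enumerate(spec.studies):
            label = f"{species}|study{st_idx + 1}"
            title = f"Population survey {st_idx + 1} of {species}"
            authors = f"Author,{sp_idx + 1}.{st_idx + 1}."
            ledger.study_style[label] = st.deposition
            ledger.study_ref_title[label] = title
            ledger.study_accessions[label] = []
            start, end = spans[st_idx]
            study_haps = [assignment[pos + k] for k in range(st.n_samples)]
            pos += st.n_samples

            if st.deposition == "unique":
                emit: list[tuple[int, int]] = []  # (haplotype index, n samples)
                for h in sorted(set(study_haps)):
                    emit.append((h, study_haps.count(h)))
            else:
                emit = [(h, 1) for h in study_haps]

            for h, n_rep in emit:
                accession = f"SY{acc_counter}.1"
                acc_counter += 1
                organism = species
                if rng.random() < spec.subspecies_rate:
                    organism = f"{species} {species.split()[-1]}"
                n_tags = int(rng.integers(1, 4))
                gene_names = [
                    spec.gene_variant_pool[
                        int(rng.integers(0, len(spec.gene_variant_pool)))
                    ]
                    for _ in range(n_tags)
                ]
                extra = "cytochrome b" if rng.random() < spec.extra_gene_rate else None
                seq = all_seqs[h][start:end]
                rec = _make_seqrecord(
                    accession, seq, organism, gene_names, title, authors, extra
                )
                seqrecords.append(rec)
                ledger.accessions.append(accession)
                ledger.haplotype_of[accession] = h
                ledger.samples_of[accession] = n_rep
                ledger.study_accessions[label].append(accession)
                ledger.item_counts[accession] = n_tags + (1 if extra else 0)
                true_freqs[h] += n_rep
                if h >= spec.n_haplotypes:
                    ledger.outlier_accessions.append(accession)
                if st.deposition == "unique":
                    magnify_counts[accession] = n_rep
                else:
                    refseq_candidates.append((accession, seq, organism))

            # a study is expected to be flagged when every sequence it
            # contributed occurs exactly once within its own contribution
            if st.deposition == "unique":
                ledger.expected_flagged_studies.append(label)
            else:
                counts = {h: study_haps.count(h) for h in set(study_haps)}
                if counts and max(counts.values()) == 1:
                    ledger.expected_flagged_studies.append(label)

        # RefSeq duplicates of already-present originals
        n_ref = min(spec.n_refseq_duplicates, len(refseq_candidates))
        if n_ref < spec.n_refseq_duplicates:
            raise ValueError(
                "not enough all-style records to duplicate as RefSeq entries"
            )
        chosen = rng.choice(len(refseq_candidates), size=n_ref, replace=False)
        for j in sorted(int(c) for c in chosen):
            src_acc, src_seq, src_org = refseq_candidates[j]
            accession = f"NC_{acc_counter}.1"
            acc_counter += 1
            rec = _make_seqrecord(
                accession,
                src_seq,
                src_org,
                ["ND2"],
                f"RefSeq curation of {species}",
                "RefSeq,Consortium.",
                refseq_source=src_acc,
            )
            seqrecords.append(rec)
            ledger.refseq_duplicates.append(accession)

        # final ground truth: magnified frequencies minus outliers
        ledger.true_haplotype_frequencies = sorted(
            (f for h, f in enumerate(true_freqs) if f and h < spec.n_haplotypes),
            reverse=True,
        )
        ledger.true_sample_total = sum(ledger.true_haplotype_frequencies)
        ledgers.append(ledger)

    gb_path = out_dir / f"{prefix}.gb"
    with open(gb_path, "w") as fh:
        SeqIO.write(seqrecords, fh, "genbank")
    fasta_path = out_dir / f"{prefix}.fasta"
    with open(fasta_path, "w") as fh:
        SeqIO.write(seqrecords, fh, "fasta")
    acc_path = out_dir / f"{prefix}_accessions.csv"
    with open(acc_path, "w") as fh:
        fh.write("accession\n")
        for rec in seqrecords:
            fh.write(rec.id + "\n")
    magnify = MagnifyTable(counts=magnify_counts)
    magnify_path = None
    if magnify_counts:
        magnify_path = out_dir / f"MAGNIFY_{prefix}.csv"
        magnify.to_csv(magnify_path)
    for ledger in ledgers:
        ledger.to_json(out_dir / f"{prefix}_{ledger.species.replace(' ', '_')}_ledger.json")
    return FixtureOutput(
        genbank_path=gb_path,
        fasta_path=fasta_path,
        magnify_path=magnify_path,
        magnify=magnify,
        ledgers=ledgers,
        accession_list_path=acc_path,
    )


def generate_trace(n: int, rho: float, seed: int = 0, name: str = "ar1") -> TraceSeries:
    """Stationary AR(1) series with lag-1 autocorrelation ``rho``.

    The theoretical ESS of such a series is n(1-rho)/(1+rho), which makes it
    a convenient probe for the ESS estimator.
    """
    if not -1 < rho < 1:
        raise ValueError("rho must satisfy |rho| < 1")
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = eps[0] / np.sqrt(1.0 - rho * rho)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + eps[t]
    return TraceSeries(name=name, values=x, burn_in=0.0)
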