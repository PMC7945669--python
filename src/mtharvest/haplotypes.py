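"""Haplotype collapse, deposition audit, frequency magnification, networks.

Haplotype frequencies drive effective-population-size estimates, so a study
that deposited only one representative accession per haplotype would bias a
skyline reconstruction.  This module collapses the cleaned alignment into a
haplotype table, flags studies whose every contributed sequence is unique
(candidates for that deposition style), restores true sampled frequencies
from a user-supplied magnification table, draws a minimum-spanning-tree
haplotype network, and removes extreme singleton outliers — haplotypes seen
once and separated from everything else by more base changes than a
user-set threshold.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import networkx as nx

from .alignment import Alignment
from .core import RecordSet, logger

PathLike = Union[str, Path]

#: Default "extreme outlier" separation: singletons more than this many base
#: changes from every other haplotype are removed.
OUTLIER_BP = 30


@dataclass
class Haplotype:
    haplotype_id: str
    sequence: str
    member_accessions: list[str]
    study_ids: set[str] = field(default_factory=set)
    # per-accession sample counts (1 until magnified)
    acc_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.acc_counts:
            self.acc_counts = {a: 1 for a in self.member_accessions}

    @property
    def frequency(self) -> int:
        return sum(self.acc_counts.values())


@dataclass
class HaplotypeTable:
    rows: list[Haplotype]
    accession_study: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seqs = [h.sequence for h in self.rows]
        if len(set(seqs)) != len(seqs):
            raise ValueError("haplotype sequences are not pairwise distinct")
        if len({len(s) for s in seqs}) > 1:
            raise ValueError("haplotype sequences have unequal lengths")

    @property
    def total_samples(self) -> int:
        return sum(h.frequency for h in self.rows)

    @property
    def n_haplotypes(self) -> int:
        return len(self.rows)

    @property
    def seq_length(self) -> int:
        return len(self.rows[0].sequence) if self.rows else 0

    def get(self, haplotype_id: str) -> Haplotype:
        for h in self.rows:
            if h.haplotype_id == haplotype_id:
                return h
        raise KeyError(haplotype_id)

    def find_by_accession(self, accession_id: str) -> Haplotype:
        for h in self.rows:
            if accession_id in h.acc_counts:
                return h
        raise KeyError(accession_id)


@dataclass
class HaplotypeNetwork:
    """Haplotype nodes joined by a minimum spanning tree of base differences."""

    nodes: list[tuple[str, int]]  # (haplotype_id, frequency)
    edges: list[tuple[str, str, int]]  # MST edges (a, b, hamming distance)
    min_dist: dict[str, int]  # nearest-neighbour distance from the FULL matrix

    @property
    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges)


@dataclass
class MagnifyTable:
    """Accession → true sampled frequency, as published in the source study."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for acc, n in self.counts.items():
            if n < 1:
                raise ValueError(f"sampled frequency for {acc} must be >= 1, got {n}")

    @classmethod
    def from_csv(cls, path: PathLike) -> "MagnifyTable":
        counts: dict[str, int] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            next(reader, None)  # header required
            for row in reader:
                if len(row) >= 2 and row[0].strip():
                    acc = row[0].strip()
                    if acc in counts:
                        raise ValueError(f"duplicate accession {acc} in magnify table")
                    counts[acc] = int(row[1])
        return cls(counts=counts)

    def to_csv(self, path: PathLike) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["accession_id", "sampled_frequency"])
            for acc, n in self.counts.items():
                writer.writerow([acc, n])


def hamming(a: str, b: str) -> int:
    """Base differences between two equal-length ungapped sequences."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def collapse_haplotypes(aln: Alignment, rs: Optional[RecordSet] = None) -> HaplotypeTable:
    """Merge identical alignment rows into haplotypes.

    Requires the cleaned (gap-free, cropped) alignment so that identity is
    well defined.  Frequency starts at the member count; study ids are
    unioned from the record set when one is supplied.
    """
    if aln.matrix and len({len(r) for r in aln.matrix}) > 1:
        raise ValueError("alignment rows have unequal lengths")
    study_of: dict[str, str] = {}
    if rs is not None:
        study_of = {r.accession_id: r.study_id for r in rs}
    groups: dict[str, list[str]] = {}
    for sid, row in zip(aln.seq_ids, aln.matrix):
        groups.setdefault(row, []).append(sid)
    rows = []
    for k, (seq, members) in enumerate(groups.items(), start=1):
        rows.append(
            Haplotype(
                haplotype_id=f"H{k}",
                sequence=seq,
                member_accessions=list(members),
                study_ids={study_of[a] for a in members if a in study_of},
            )
        )
    ht = HaplotypeTable(rows=rows, accession_study=study_of)
    logger.info(
        "collapse_haplotypes: %d haplotypes from %d sequences",
        ht.n_haplotypes,
        aln.nrow,
    )
    return ht


def flag_unique_only_studies(ht: HaplotypeTable) -> list[str]:
    """Studies whose every contributed sequence is a within-study unique.

    Such studies may have deposited one accession per haplotype rather than
    one per individual; they need manual review (and, where confirmed, a
    magnification table) before skyline analysis.
    """
    per_study: dict[str, list[int]] = {}
    for h in ht.rows:
        counts: dict[str, int] = {}
        for acc, n in h.acc_counts.items():
            study = ht.accession_study.get(acc, "")
            counts[study] = counts.get(study, 0) + n
        for study, n in counts.items():
            per_study.setdefault(study, []).append(n)
    flagged = sorted(
        study for study, counts in per_study.items() if max(counts) == 1
    )
    if flagged:
        logger.warning(
            "flag_unique_only_studies: %d studies contributed only unique "
            "haplotypes: %s",
            len(flagged),
            ", ".join(flagged),
        )
    return flagged


def magnify_to_sampled_freq(ht: HaplotypeTable, mt: MagnifyTable) -> HaplotypeTable:
    """Raise accession contributions to their published sampled frequencies.

    After magnification the accession listed for ``n`` individuals counts as
    ``n`` samples of its haplotype.  Lowering a contribution is refused —
    the magnification table is a record of extra samples, not a resampler.
    """
    for acc, n in mt.counts.items():
        try:
            h = ht.find_by_accession(acc)
        except KeyError:
            raise KeyError(
                f"magnify table accession {acc} is not in the haplotype table"
            ) from None
        current = h.acc_counts[acc]
        if n < current:
            raise ValueError(
                f"sampled frequency {n} for {acc} is below its current "
                f"contribution {current}"
            )
        h.acc_counts[acc] = n
    logger.info(
        "magnify_to_sampled_freq: total samples now %d", ht.total_samples
    )
    return ht


def build_haplotype_network(ht: HaplotypeTable) -> HaplotypeNetwork:
    """Minimum-spanning-tree haplotype network on Hamming distances.

    Edges are considered in (distance, id, id) order so ties break
    deterministically.  ``min_dist`` is each haplotype's distance to its
    nearest neighbour in the full distance matrix, not merely along tree
    edges.
    """
    if not ht.rows:
        raise ValueError("cannot build a network from an empty haplotype table")
    ids = [h.haplotype_id for h in ht.rows]
    seq = {h.haplotype_id: h.sequence for h in ht.rows}
    if len(ids) == 1:
        return HaplotypeNetwork(
            nodes=[(ids[0], ht.rows[0].frequency)], edges=[], min_dist={}
        )
    g = nx.Graph()
    g.add_nodes_from(ids)
    all_edges = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            u, v = sorted((a, b))
            all_edges.append((hamming(seq[a], seq[b]), u, v))
    all_edges.sort()
    for w, u, v in all_edges:
        g.add_edge(u, v, weight=w)
    mst = nx.minimum_spanning_edges(g, algorithm="kruskal", data=True)
    edges = sorted((min(u, v), max(u, v), d["weight"]) for u, v, d in mst)
    min_dist: dict[str, int] = {}
    for w, u, v in all_edges:
        min_dist[u] = min(min_dist.get(u, w), w)
        min_dist[v] = min(min_dist.get(v, w), w)
    return HaplotypeNetwork(
        nodes=[(h.haplotype_id, h.frequency) for h in ht.rows],
        edges=edges,
        min_dist=min_dist,
    )


def drop_outliers(
    ht: HaplotypeTable,
    threshold: int = OUTLIER_BP,
    fasta_path: Optional[PathLike] = None,
) -> tuple[HaplotypeTable, list[str]]:
    """Remove extreme singleton outliers from the haplotype table.

    A haplotype is an outlier when its frequency is 1 AND its nearest other
    haplotype is strictly more than ``threshold`` base changes away.
    Removals are processed one at a time, most divergent first, with
    nearest-neighbour distances recomputed after each removal, so the result
    does not depend on input order.  When ``fasta_path`` is given, the
    surviving sequences are written out (one entry per member accession) for
    downstream analysis.
    """
    if threshold < 0:
        raise ValueError("outlier threshold must be >= 0")
    current = ht
    removed: list[str] = []
    while current.n_haplotypes >= 2:
        net = build_haplotype_network(current)
        candidates = [
            h
            for h in current.rows
            if h.frequency == 1 and net.min_dist[h.haplotype_id] > threshold
        ]
        if not candidates:
            break
        worst = max(
            candidates, key=lambda h: (net.min_dist[h.haplotype_id], h.haplotype_id)
        )
        removed.append(worst.haplotype_id)
        logger.warning(
            "drop_outliers: removed singleton %s (accessions %s) at distance %d",
            worst.haplotype_id,
            ",".join(worst.member_accessions),
            net.min_dist[worst.haplotype_id],
        )
        current = HaplotypeTable(
            rows=[h for h in current.rows if h.haplotype_id != worst.haplotype_id],
            accession_study=current.accession_study,
        )
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for h in current.rows:
                for acc in h.member_accessions:
                    fh.write(f">{acc}\n")
                    for i in range(0, len(h.sequence), 70):
                        fh.write(h.sequence[i : i + 70] + "\n")
    return current, removed


def write_haplotype_table(ht: HaplotypeTable, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["haplotype_id", "frequency", "member_accessions", "study_ids", "sequence"]
        )
        for h in ht.rows:
            writer.writerow(
                [
                    h.haplotype_id,
                    h.frequency,
                    ";".join(h.member_accessions),
                    ";".join(sorted(h.study_ids)),
                    h.sequence,
                ]
            )


def write_network_edgelist(net: HaplotypeNetwork, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["from", "to", "distance"])
        for a, b, w in net.edges:
            writer.writerow([a, b, w])


def clade_size_summary(net: HaplotypeNetwork, split_bp: int = 5) -> list[int]:
    """Sizes (total sample counts) of network components after cutting every
    MST edge longer than ``split_bp`` — a quick sub-structure indicator.

    Large, deeply separated components hint at population sub-structure,
    which violates the panmixia assumption of skyline models; the summary is
    reported for manual review, never acted on automatically.
    """
    g = nx.Graph()
    freq = dict(net.nodes)
    g.add_nodes_from(freq)
    for a, b, w in net.edges:
        if w <= split_bp:
            g.add_edge(a, b)
    sizes = sorted(
        (sum(freq[n] for n in comp) for comp in nx.connected_components(g)),
        reverse=True,
    )
    return sizes


def plot_network(net: HaplotypeNetwork, path: PathLike, seed: int = 0) -> None:
    """Draw the MST haplotype network, node area scaled to frequency."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = nx.Graph()
    freq = dict(net.nodes)
    g.add_nodes_from(freq)
    for a, b, w in net.edges:
        g.add_edge(a, b, weight=w)
    pos = nx.spring_layout(g, seed=seed, weight=None)
    fig, ax = plt.subplots(figsize=(6, 6))
    sizes = [60 + 40 * freq[n] for n in g.nodes]
    nx.draw_networkx(g, pos=pos, ax=ax, node_size=sizes, font_size=6)
    nx.draw_networkx_edge_labels(
        g, pos=pos, ax=ax, edge_labels={(a, b): w for a, b, w in net.edges}, font_size=6
    )
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
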