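"""Independent oracles and small builders shared across the test suite.

The oracles here deliberately avoid the implementation's algorithms:
alignment scores come from exhaustive enumeration over monotone matchings,
spanning-tree weights from enumeration over all edge subsets, and study
flags from a direct per-study recount.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from mtharvest.haplotypes import Haplotype, HaplotypeTable

BASES = "ACGT"


def enumeration_alignment_score(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> int:
    """Best semi-global alignment score by exhaustive enumeration.

    Every alignment corresponds to a monotone matching between positions of
    ``a`` and ``b``; unmatched characters between matched columns are
    internal gaps, and of the two overhangs on each end only the shorter one
    can ride free, so the other is charged.  Feasible only for short
    sequences (the number of matchings is sum_k C(n,k)·C(m,k)).
    """
    n, m = len(a), len(b)
    best = 0  # empty overlap: both sequences ride the free boundary
    for k in range(1, min(n, m) + 1):
        for ia in combinations(range(n), k):
            for jb in combinations(range(m), k):
                s = sum(
                    match if a[i] == b[j] else mismatch for i, j in zip(ia, jb)
                )
                internal = (ia[-1] - ia[0] + 1 - k) + (jb[-1] - jb[0] + 1 - k)
                lead = min(ia[0], jb[0])
                trail = min(n - 1 - ia[-1], m - 1 - jb[-1])
                s += gap * (internal + lead + trail)
                if s > best:
                    best = s
    return best


def brute_force_mst_weight(n: int, dist) -> int:
    """Minimum spanning-tree weight by enumeration over all edge subsets."""
    if n <= 1:
        return 0
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = None
    for subset in combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for i, j in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if not ok:
            continue
        w = sum(dist(i, j) for i, j in subset)
        if best is None or w < best:
            best = w
    return best


def brute_force_flagged_studies(ht: HaplotypeTable) -> set[str]:
    """Per-study recount: flagged iff no haplotype is sampled twice within."""
    samples: dict[str, list[str]] = {}
    for h in ht.rows:
        for acc, count in h.acc_counts.items():
            study = ht.accession_study.get(acc, "")
            samples.setdefault(study, []).extend([h.haplotype_id] * count)
    return {
        study
        for study, haps in samples.items()
        if all(haps.count(h) == 1 for h in haps)
    }


def random_fixture_spec(seed: int):
    """Randomised study-structured fixture spec, deterministic in ``seed``."""
    from mtharvest.fixtures import FixtureSpec, StudySpec

    rng = np.random.default_rng(seed)
    n_studies = int(rng.integers(2, 4))
    studies = [StudySpec(n_samples=int(rng.integers(5, 11))) for _ in range(n_studies)]
    if rng.random() < 0.5:
        studies[-1] = StudySpec(
            n_samples=studies[-1].n_samples, deposition="unique"
        )
    return FixtureSpec(
        seed=seed,
        studies=tuple(studies),
        n_haplotypes=int(rng.integers(2, 6)),
        n_refseq_duplicates=int(rng.integers(0, 3)),
        n_outliers=int(rng.integers(0, 2)),
        gene_length=480,
        subspecies_rate=float(rng.uniform(0, 0.4)),
    )


def assert_pipeline_recovers_ledger(seed: int, tmp_path) -> None:
    """Generate a fixture, run the full pipeline, compare with the ledger."""
    from mtharvest import FilterThresholds
    from mtharvest.fixtures import generate_records
    from mtharvest.pipeline import PipelineConfig, run_pipeline

    spec = random_fixture_spec(seed)
    out = generate_records(spec, tmp_path / f"fx{seed}")
    cfg = PipelineConfig(
        genbank_path=out.genbank_path,
        out_dir=tmp_path / f"fx{seed}" / "out",
        magnify_path=out.magnify_path,
        thresholds=FilterThresholds(0, 0, 0),
        minbp=spec.gene_length // 2,  # every study span covers the core half
        # stand-in for the manual review step: small all-samples studies can
        # legitimately be all-unique, and the generator's ledger knows it
        acknowledge_unique_studies=True,
    )
    result = run_pipeline(cfg)
    ledger = out.ledgers[0]

    # RefSeq duplicates removed exactly
    final_accs = set(result.record_set.accession_ids())
    assert final_accs == set(ledger.accessions)
    assert not any("_" in a for a in final_accs)

    sp = result.species[ledger.species]
    # haplotype frequency spectrum recovered exactly
    assert (
        sorted((h.frequency for h in sp.haplotype_table.rows), reverse=True)
        == ledger.true_haplotype_frequencies
    )
    assert sp.alignment.ncol == ledger.expected_seq_length
    # outliers removed exactly
    surviving = {
        a for h in sp.haplotype_table.rows for a in h.member_accessions
    }
    assert set(ledger.accessions) - surviving == set(ledger.outlier_accessions)
    # flagged studies match the generator's expectation
    study_id_of = {}
    for label, accs in ledger.study_accessions.items():
        study_id_of[label] = result.record_set.get(accs[0]).study_id
    expected_flags = {study_id_of[l] for l in ledger.expected_flagged_studies}
    assert set(sp.flagged_studies) == expected_flags


def random_sequences(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Distinct random nucleotide strings of one length."""
    seen: set[str] = set()
    while len(seen) < n:
        seen.add("".join(rng.choice(list(BASES), size=length)))
    return sorted(seen)


def make_haplotype_table(
    sequences: list[str],
    frequencies: list[int],
    studies: list[str] | None = None,
) -> HaplotypeTable:
    """Haplotype table with one synthetic member accession per sample."""
    rows = []
    acc_study: dict[str, str] = {}
    acc = 0
    for k, (seq, freq) in enumerate(zip(sequences, frequencies), start=1):
        members = []
        for _ in range(freq):
            name = f"T{acc:05d}.1"
            members.append(name)
            acc_study[name] = studies[k - 1] if studies else "studyA"
            acc += 1
        rows.append(
            Haplotype(haplotype_id=f"H{k}", sequence=seq, member_accessions=members)
        )
    return HaplotypeTable(rows=rows, accession_study=acc_study)
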