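# Methods

This note documents the models, rules and numerical choices behind each
pipeline stage, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Records and RefSeq deduplication

A repository search can return the same sample twice: the original
submission and a curated RefSeq copy. RefSeq accessions always contain an
underscore; plain repository accessions never do, so recognition is exact.
A RefSeq record is removed only when the original it duplicates is present
in the set. Resolution order:

1. the cross-reference declared in the record itself (DBSOURCE field or a
   COMMENT of the form "…derived from ACC…");
2. failing a declared source, an exact sequence + organism match against a
   non-RefSeq record.

A RefSeq record with no present original is **retained** — dropping it
would silently discard the only copy of the data. The operation is
idempotent.

Each record's `study_id` is a short hash of its first REFERENCE block's
title and authors; records with no reference get `unknown:<accession>`.
This is the grouping key for the deposition-style audit, so two studies
with byte-identical reference blocks would merge — acceptable for curation
purposes, where the cost of a false merge is one extra manual review.

## Nomenclature standardisation

Gene-name matching case-folds and strips punctuation and whitespace
(`" .,-_'()/"`) before comparison, so `nad2`, `NADH2`, and `ND-2` all hit
`ND2`. No fuzzy matching is attempted: misspellings beyond punctuation are
reported as unmatched rather than guessed. The bundled conversion table
covers 18 commonly sequenced mitochondrial loci (ND1–ND6, ND4L, COX1–3,
ATP6, ATP8, CYTB, 12S, 16S, the control region, tRNA-Phe and tRNA-Val);
its variant lists were assembled from standard mitochondrial nomenclature
and the table is fully user-replaceable, since no fixed list survives
contact with a new clade's deposition habits.

Organism names with three or more tokens are truncated to the first two
(subspecies → species), except when a hybrid or open-nomenclature marker
(`x`, `sp.`, `cf.`, `aff.`) is present — those records are left untouched
and flagged for manual review, because truncation could merge distinct
taxa. Explicit old-name → new-name map entries override truncation.

## Alignment

Same-gene mtDNA sequences from different studies are near-identical but
cover different spans, so the aligner is built around that case:

* **Center-star construction.** The longest sequence (ties: smallest
  accession lexicographically) is the center; every other sequence is
  aligned to it pairwise and the alignments are merged under
  once-a-gap-always-a-gap. Insertion runs at the same center position from
  different sequences are stacked into shared columns abutting the center;
  they are not claimed to be homologous. For the near-identical inputs this
  pipeline handles, center-star is effectively exact; users who prefer a
  full progressive MSA can import an external FASTA alignment instead
  (`import_external_alignment`, `--external-alignment`).
* **Semi-global pairwise DP.** Match +1, mismatch −1, gap −2 (linear, all
  configurable), with **terminal gaps free**. Penalised end gaps are the
  wrong model when one sequence is a sub-span of another: they drag in
  spurious terminal matches and internal gaps. Traceback ties resolve
  diagonal > up > left and the terminal cell prefers the full-overlap
  corner, so results are deterministic. The implementation is verified
  against exhaustive enumeration over all monotone position matchings for
  short sequences.
* **Overlap cropping.** All rows are cut to
  [max of first covered columns, min of last covered columns], iterated to
  a fixed point (an internal deletion at the window edge can expose a new
  overhang). Per-row bp losses are logged and losses above 500 bp flagged:
  that pattern usually means one short sequence is dragging the window in,
  and the right fix is removing that sequence, not accepting the crop.
* **Cleaning.** Every column containing a gap, `N`, `?` or any non-ACGT
  IUPAC code in any row is deleted. Multi-study data mixes sequencing
  technologies and eras; per-column deletion of anything ambiguous is the
  only rule that treats all studies evenhandedly. Coordinates are 1-based
  inclusive throughout.

## Haplotypes, deposition audit, outliers

Identical cleaned rows collapse into haplotypes carrying member accessions
and per-accession sample counts. A study is flagged when **every** sequence
it contributed occurs exactly once within its own contribution — the
signature of a unique-haplotypes-only depositor, though small all-samples
studies trigger it legitimately. Because haplotype frequencies drive
skyline estimates, the pipeline treats unresolved flags as a hard stop: the
run halts unless a magnification table covers the flagged accessions or the
configuration explicitly records that the flags were reviewed.

Magnification raises an accession's contribution to its published sampled
frequency (a `1 → 50` entry turns one deposited haplotype into 50 samples).
Lowering a contribution is refused.

The haplotype network is a minimum spanning tree on pairwise Hamming
distances, built by Kruskal's algorithm with edges pre-sorted by
(distance, id, id) for deterministic tie-breaking; tree weight is verified
against exhaustive spanning-tree enumeration for small tables. Each node's
`min_dist` — the distance to its nearest other haplotype — comes from the
full distance matrix, not just tree edges. An **extreme outlier** is a
haplotype with frequency 1 and `min_dist` strictly greater than the
threshold (default 30 bp). Removals proceed most-divergent-first with
`min_dist` recomputed after each removal, making the result order
independent; two divergent singletons that are close to *each other* are
not outliers and survive. The network plus a clade-size summary (component
sample totals after cutting long edges) are reported as a sub-structure
diagnostic; the package never splits a dataset automatically, because
over-splitting manufactures spurious expansion signals.

## Information-content filters

A species dataset is dropped when haplotypes < 6, samples < 20 or
alignment length < 600 bp, with *all* failing reasons reported. Boundary
semantics are strictly-less-than: exactly 6/20/600 passes. The three
predicates are independent (they commute; the retained set is monotone
non-increasing in every threshold — both property-tested). The defaults
suit a single-gene avian analysis and are deliberately exposed: no
out-of-the-box value is right for every gene, mutation rate or sample
budget.

## BEAST2 XML and run post-processing

`setup_basic_xml` writes a BEAST 2.6-dialect document: the cleaned
alignment verbatim, a coalescent Bayesian skyline tree prior (default 5
groups), a strict clock fixed at the user's substitution rate, and
trace/tree loggers named from the output stem. The default site model is
HKY with empirical base frequencies — a package choice, not a mandate;
JC69 and GTR are selectable. Validation is by parse-ability and
round-trip (sequences, taxa, rate, chain length recoverable exactly), not
byte equality, since element naming drifts across BEAST2 minor versions.
The substitution rate is a plain user input; taxon-specific calibrations
(e.g. body-mass corrections) are out of scope and should be computed
upstream.

ESS uses the standard autocorrelation estimator
ESS = n / (1 + 2 Σ ρ̂_k) with the initial-positive-sequence truncation:
autocorrelations are summed in adjacent pairs Γ_m = ρ̂_{2m} + ρ̂_{2m+1}
while the pair sums remain positive. A constant series returns 1 by
convention; estimates are clipped to [1, n]; everything below 200 is
flagged. Default burn-in is 10%. Calibration: 10,000 i.i.d. draws estimate
within [8,000, 12,000], and a stationary AR(1) series with lag-1
autocorrelation ρ matches the closed form n(1−ρ)/(1+ρ) within 20%.

Skyline summaries are read from Tracer-style exports (tab or comma
delimited; column headers matched case-insensitively with common aliases),
validated (lower ≤ median ≤ upper per row, strictly increasing times), and
plotted as a dashed median with a shaded 95% HPD envelope.

## Synthetic-data generator

`mtharvest.fixtures` emits GenBank flat files with a ground-truth ledger.
What it emulates: species/subspecies name variants (default rate 0.2),
gene-name spelling variation across `gene`/`CDS`/`misc_feature` tags,
occasional extra non-target gene items, RefSeq duplicates with declared
source cross-references, per-study sequence spans, study-structured
haplotype frequencies, unique-haplotypes-only deposition (with the true
counts written to a MAGNIFY table), and divergent singleton outliers
(default 35 bp from everything).

Construction guarantees make the ledger exact rather than approximate:

* sequences are point-mutated copies of one random ancestor, so all
  Hamming distances are known by construction;
* every study span contains a central core region, and all mutated sites
  sit inside it, at least 3 bp from any span edge (a variant on a terminal
  aligned base is ambiguous with a gap+shift alignment path);
* outlier substitutions sit on a ≥ 6 bp grid, keeping them isolated point
  differences — clustered substitutions can genuinely realign as indels,
  which would change cropped lengths unpredictably;
* one all-samples study sequences the whole gene, anchoring the alignment
  so the center is always a typical haplotype;
* haplotype and outlier mutation sets are disjoint, so outlier–haplotype
  distances equal divergence + haplotype mutation count.

Output is byte-identical for a given spec and seed. Default shape: one
species, two studies (10 + 8 samples), 4 haplotypes, a 480 bp gene.

What it does **not** emulate: indels and length polymorphism, sequencing
error and ambiguity codes in the emitted sequences (ambiguity handling is
exercised by separately constructed alignments), coalescent genealogies
(frequencies are drawn, not evolved), NUMTs, re-sequenced museum
specimens, or taxonomic misidentification. Passing the end-to-end recovery
tests therefore demonstrates correct bookkeeping and algorithmic behaviour
under controlled pathologies — not robustness to every artefact of real
repository data.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` favour many small, exactly
checkable instances: oracle comparisons use sequences of length ≤ 8
(exhaustive alignment enumeration) and haplotype tables of ≤ 6 entries
(exhaustive spanning-tree enumeration); end-to-end recovery runs dozens of
seeded datasets of 10–30 records over a 480 bp gene; the RefSeq worked
example uses a 525-record set. These sizes give exact, deterministic
oracles; the algorithms themselves have no small-size assumptions, and the
aligner has been run on multi-kilobase inputs in the worked examples.

## Known limitations

* Center-star alignment does not model true insertions well when they are
  shared by a subset of sequences; for indel-rich loci (e.g. the control
  region), import an external MSA.
* Duplicate detection is limited to RefSeq accessions; re-sequenced
  specimens deposited under fresh accessions cannot be identified
  programmatically from the records alone.
* The deposition-style audit is a heuristic: small all-samples studies are
  flagged too, and resolution is intentionally manual.
* Network retrieval is out of scope; the `fetch` verb only shells out to a
  user-configured downloader.
* HPD computation from posterior tree files, model averaging and running
  the MCMC itself are out of scope — the package prepares inputs for and
  consumes outputs of BEAST2/Tracer, it does not replace them.
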