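"""Length filtering, center-star alignment, overlap cropping and cleaning.

Same-gene mitochondrial sequences from different studies are near-identical
but cover different spans of the gene.  The pipeline therefore (1) drops
sequences too short to be informative, (2) builds a multiple alignment,
(3) crops every sequence to the window covered by all of them, and
(4) deletes any remaining column holding a gap or ambiguity code, leaving a
rectangular, gap-free block on which haplotypes can be compared site by site.

The aligner is a center-star construction: the longest sequence is the
center, every other sequence is aligned to it by global dynamic programming,
and the pairwise alignments are merged under the once-a-gap-always-a-gap
rule.  For near-identical sequences this is essentially exact, and it keeps
the pipeline free of external alignment programs; an externally produced
FASTA alignment can be imported instead via :func:`import_external_alignment`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .core import RecordSet, logger

PathLike = Union[str, Path]

GAP = "-"
#: IUPAC nucleotide codes plus '?' (missing data); anything else is rejected.
IUPAC_CHARS = set("ACGTURYSWKMBDHVN?")
UNAMBIGUOUS = set("ACGT")

#: A sequence losing more than this many bp to overlap cropping is flagged.
HEAVY_LOSS_BP = 500


@dataclass
class Alignment:
    """Rectangular gapped alignment with per-row provenance."""

    seq_ids: list[str]
    matrix: list[str]
    trim_log: dict[str, int] = field(default_factory=dict)  # bp lost per row
    n_ambiguous_removed: int = 0

    def __post_init__(self) -> None:
        if len(self.seq_ids) != len(self.matrix):
            raise ValueError("seq_ids and matrix length mismatch")
        if len({len(row) for row in self.matrix}) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def ncol(self) -> int:
        return len(self.matrix[0]) if self.matrix else 0

    @property
    def nrow(self) -> int:
        return len(self.matrix)

    def coverage(self) -> list[tuple[int, int]]:
        """Per-row (first, last) non-gap column, 1-based inclusive."""
        spans = []
        for sid, row in zip(self.seq_ids, self.matrix):
            stripped = row.strip(GAP)
            if not stripped:
                raise ValueError(f"row {sid} is all gaps")
            first = len(row) - len(row.lstrip(GAP)) + 1
            last = len(row.rstrip(GAP))
            spans.append((first, last))
        return spans

    def row(self, seq_id: str) -> str:
        return self.matrix[self.seq_ids.index(seq_id)]

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def is_clean(self) -> bool:
        return all(set(row) <= UNAMBIGUOUS for row in self.matrix)


@dataclass
class LengthSummary:
    """Original sequence lengths and the maximum-overlap window width."""

    original_lengths: dict[str, int]
    overlap_length: int
    bp_lost: dict[str, int] = field(default_factory=dict)
    heavily_trimmed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.original_lengths and self.overlap_length > min(
            self.original_lengths.values()
        ):
            raise ValueError("overlap_length exceeds the shortest input")

    def histogram_table(self, bin_width: int = 50) -> pd.DataFrame:
        """Bin the original lengths for the trimming-diagnostic histogram."""
        lengths = pd.Series(list(self.original_lengths.values()), dtype=int)
        lo = (lengths.min() // bin_width) * bin_width
        hi = ((lengths.max() // bin_width) + 1) * bin_width
        bins = range(int(lo), int(hi) + bin_width, bin_width)
        counts = pd.cut(lengths, bins=list(bins), right=False).value_counts().sort_index()
        return pd.DataFrame(
            {
                "bin_start": [iv.left for iv in counts.index],
                "bin_end": [iv.right for iv in counts.index],
                "count": counts.values,
            }
        )


def drop_short_sequences(rs: RecordSet, minbp: int = 200) -> RecordSet:
    """Remove records shorter than ``minbp`` (strictly less than)."""
    if minbp < 0:
        raise ValueError("minbp must be >= 0")
    kept, dropped = [], []
    for r in rs:
        (kept if r.seq_length >= minbp else dropped).append(r)
    if dropped:
        logger.info(
            "drop_short_sequences: removed %d records < %d bp: %s",
            len(dropped),
            minbp,
            ", ".join(r.accession_id for r in dropped),
        )
    return rs.replace_records(f"drop_short_sequences[minbp={minbp}]", kept)


def pairwise_align(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> tuple[str, str, int]:
    """Semi-global dynamic-programming alignment of two sequences.

    Linear gap penalty inside the alignment; terminal gaps are free, because
    same-gene sequences from different studies routinely cover different
    spans and penalising the overhangs drags in spurious end matches.
    Traceback ties resolve diagonal > up > left, and the terminal cell
    prefers the full-overlap corner, so the result is deterministic.
    Returns the two gapped strings and the score of the aligned region.
    """
    n, m = len(a), len(b)
    # DP with free leading gaps: first row/column are zero
    rows: list[list[int]] = [[0] * (m + 1)]
    pointers = [bytearray(m + 1) for _ in range(n + 1)]
    pointers[0][1:] = bytes([2]) * m
    for i in range(1, n + 1):
        ai = a[i - 1]
        cur = [0] * (m + 1)
        ptr_row = pointers[i]
        ptr_row[0] = 1
        prev_row = rows[i - 1]
        for j in range(1, m + 1):
            diag = prev_row[j - 1] + (match if ai == b[j - 1] else mismatch)
            up = prev_row[j] + gap
            left = cur[j - 1] + gap
            if diag >= up and diag >= left:
                cur[j] = diag  # ptr 0
            elif up >= left:
                cur[j] = up
                ptr_row[j] = 1
            else:
                cur[j] = left
                ptr_row[j] = 2
        rows.append(cur)
    # free trailing gaps: best cell on the bottom row / right column,
    # preferring the corner, then the right column bottom-up, then the
    # bottom row right-to-left
    end_i, end_j = n, m
    best = rows[n][m]
    for i in range(n - 1, -1, -1):
        if rows[i][m] > best:
            best, end_i, end_j = rows[i][m], i, m
    for j in range(m - 1, -1, -1):
        if rows[n][j] > best:
            best, end_i, end_j = rows[n][j], n, j
    out_a: list[str] = [GAP] * (m - end_j) + list(a[end_i:])
    out_b: list[str] = list(b[end_j:]) + [GAP] * (n - end_i)
    out_a.reverse()
    out_b.reverse()
    i, j = end_i, end_j
    while i > 0 and j > 0:
        p = pointers[i][j]
        if p == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif p == 1:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
    # free leading overhang
    out_a.extend(list(a[:i][::-1]) + [GAP] * j)
    out_b.extend([GAP] * i + list(b[:j][::-1]))
    return "".join(reversed(out_a)), "".join(reversed(out_b)), best


def _validate_sequences(seqs: dict[str, str]) -> None:
    for sid, seq in seqs.items():
        bad = set(seq.upper()) - IUPAC_CHARS
        if bad:
            raise ValueError(
                f"sequence {sid} contains non-IUPAC characters: "
                f"{', '.join(sorted(bad))}"
            )


def align_sequences(
    seqs: dict[str, str],
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> Alignment:
    """Center-star multiple alignment of same-gene sequences.

    The center is the longest sequence (ties broken by lexicographically
    smallest id).  Every other sequence is aligned to the center pairwise and
    merged: a gap introduced into the center in any pairwise step is
    propagated to all rows (once a gap, always a gap).
    """
    if len(seqs) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    seqs = {sid: s.upper() for sid, s in seqs.items()}
    _validate_sequences(seqs)

    center_id = min(seqs, key=lambda sid: (-len(seqs[sid]), sid))
    center = seqs[center_id]
    others = [sid for sid in seqs if sid != center_id]
    nc = len(center)

    # per-row decomposition against the center: one character (or gap) per
    # center position, plus inserted runs before each center position
    # (index nc = trailing insertions)
    row_chars: dict[str, list[str]] = {center_id: list(center)}
    row_ins: dict[str, list[str]] = {center_id: [""] * (nc + 1)}
    for sid in others:
        ca, sa, _ = pairwise_align(center, seqs[sid], match, mismatch, gap)
        chars: list[str] = []
        ins: list[list[str]] = [[] for _ in range(nc + 1)]
        t = 0
        for x, y in zip(ca, sa):
            if x == GAP:
                ins[t].append(y)
            else:
                chars.append(y)
                t += 1
        row_chars[sid] = chars
        row_ins[sid] = ["".join(run) for run in ins]

    # once a gap, always a gap: every insertion run opens columns for all
    # rows; runs at the same center position are right-aligned so they abut
    # the center (they are not claimed to be homologous)
    ordered_ids = list(seqs)  # input order
    out: dict[str, list[str]] = {sid: [] for sid in ordered_ids}
    for t in range(nc + 1):
        width = max(len(row_ins[sid][t]) for sid in ordered_ids)
        if width:
            for sid in ordered_ids:
                run = row_ins[sid][t]
                # abut the center: right-align runs before it, left-align
                # the trailing block
                padded = run.rjust(width, GAP) if t < nc else run.ljust(width, GAP)
                out[sid].append(padded)
        if t < nc:
            for sid in ordered_ids:
                out[sid].append(row_chars[sid][t])
    aln = Alignment(
        seq_ids=ordered_ids, matrix=["".join(out[sid]) for sid in ordered_ids]
    )
    logger.info(
        "align_sequences: %d sequences, center %s, %d columns",
        aln.nrow,
        center_id,
        aln.ncol,
    )
    return aln


def crop_to_overlap(
    aln: Alignment,
    rs: Optional[RecordSet] = None,
    heavy_loss_bp: int = HEAVY_LOSS_BP,
) -> tuple[Alignment, LengthSummary]:
    """Crop all rows to the window covered by every sequence.

    The window is [max over rows of first covered column, min over rows of
    last covered column].  The returned summary records each row's bp lost;
    rows losing more than ``heavy_loss_bp`` are flagged — typically the
    signature of one much shorter sequence dragging the window in.
    """
    cropped = list(aln.matrix)
    # iterate to a fixed point: trimming can expose a new leading/trailing
    # gap when a row has an internal deletion at the window edge
    while True:
        spans = Alignment(seq_ids=list(aln.seq_ids), matrix=cropped).coverage()
        lo = max(s[0] for s in spans)
        hi = min(s[1] for s in spans)
        if lo > hi:
            raise ValueError(
                "empty overlap window: some sequences do not overlap at all; "
                "remove non-overlapping sequences and re-align"
            )
        if lo == 1 and hi == len(cropped[0]):
            break
        cropped = [row[lo - 1 : hi] for row in cropped]
    original = {
        sid: len(row.replace(GAP, "")) for sid, row in zip(aln.seq_ids, aln.matrix)
    }
    bp_lost = {
        sid: original[sid] - len(crow.replace(GAP, ""))
        for sid, crow in zip(aln.seq_ids, cropped)
    }
    heavy = sorted(sid for sid, lost in bp_lost.items() if lost > heavy_loss_bp)
    if heavy:
        logger.warning(
            "crop_to_overlap: %d sequences lost > %d bp: %s",
            len(heavy),
            heavy_loss_bp,
            ", ".join(heavy),
        )
    out = Alignment(
        seq_ids=list(aln.seq_ids),
        matrix=cropped,
        trim_log={sid: aln.trim_log.get(sid, 0) + bp_lost[sid] for sid in aln.seq_ids},
        n_ambiguous_removed=aln.n_ambiguous_removed,
    )
    if rs is not None:
        lengths = {r.accession_id: r.seq_length for r in rs if r.accession_id in original}
    else:
        lengths = original
    summary = LengthSummary(
        original_lengths=lengths,
        overlap_length=out.ncol,
        bp_lost=bp_lost,
        heavily_trimmed=heavy,
    )
    return out, summary


def remove_ambiguous_columns(aln: Alignment) -> Alignment:
    """Delete every column holding a gap, 'N', '?' or other non-ACGT code."""
    keep = [
        c
        for c in range(aln.ncol)
        if all(row[c] in UNAMBIGUOUS for row in aln.matrix)
    ]
    n_removed = aln.ncol - len(keep)
    if not keep:
        raise ValueError("no columns remain after removing ambiguous sites")
    matrix = ["".join(row[c] for c in keep) for row in aln.matrix]
    if n_removed:
        logger.info("remove_ambiguous_columns: deleted %d columns", n_removed)
    return Alignment(
        seq_ids=list(aln.seq_ids),
        matrix=matrix,
        trim_log=dict(aln.trim_log),
        n_ambiguous_removed=aln.n_ambiguous_removed + n_removed,
    )


def summarise_lengths(
    lengths: dict[str, int], overlap_length: int
) -> LengthSummary:
    """Build the trimming-diagnostic summary (histogram + overlap marker)."""
    return LengthSummary(original_lengths=dict(lengths), overlap_length=overlap_length)


def plot_length_histogram(
    summary: LengthSummary, path: PathLike, bin_width: int = 50
) -> None:
    """Histogram of original lengths with the overlap window marked in red."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    lengths = list(summary.original_lengths.values())
    lo = (min(lengths) // bin_width) * bin_width
    hi = ((max(lengths) // bin_width) + 1) * bin_width
    ax.hist(lengths, bins=range(lo, hi + bin_width, bin_width), edgecolor="black")
    ax.axvline(summary.overlap_length, color="red", linewidth=2)
    ax.set_xlabel("Sequence length (bp)")
    ax.set_ylabel("Number of sequences")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def write_alignment_fasta(aln: Alignment, path: PathLike) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.seq_ids, aln.matrix):
            fh.write(f">{sid}\n")
            for i in range(0, len(row), 70):
                fh.write(row[i : i + 70] + "\n")


def import_external_alignment(path: PathLike) -> Alignment:
    """Load an externally produced FASTA alignment (e.g. from MAFFT)."""
    from Bio import SeqIO

    seq_ids, matrix = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_ids.append(rec.id)
        matrix.append(str(rec.seq).upper())
    if not seq_ids:
        raise ValueError(f"no sequences in alignment file {path}")
    return Alignment(seq_ids=seq_ids, matrix=matrix)
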