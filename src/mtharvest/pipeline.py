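"""End-to-end orchestration: flat file in, skyline-ready XML out.

Stage order: parse -> RefSeq dedup -> nomenclature standardisation -> gene
filter -> length filter -> per-species alignment -> overlap crop -> ambiguity
clean -> haplotype collapse -> deposition-style flags -> frequency
magnification -> network/outliers -> information-content filters -> BEAST2
XML.  Every stage appends counts to a provenance report; re-running the same
configuration on the same inputs reproduces the report byte for byte.

Studies flagged as possible unique-haplotype depositors are a hard stop:
either a magnification table covers their accessions or the configuration
explicitly acknowledges that the flags were reviewed.  Silent continuation
would feed biased haplotype frequencies straight into the skyline model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import alignment as aln_mod
from . import beast_io, filters, haplotypes, records_io, standardise
from .core import RecordSet, logger

PathLike = Union[str, Path]


class PipelineHalt(RuntimeError):
    """Raised when a stage needs manual resolution; carries provenance."""

    def __init__(self, stage: str, message: str, report_lines: list[str]):
        super().__init__(f"pipeline halted at stage {stage!r}: {message}")
        self.stage = stage
        self.report_lines = report_lines


@dataclass
class PipelineConfig:
    genbank_path: PathLike
    out_dir: PathLike
    gene: str = "ND2"
    minbp: int = 200
    outlier_bp: int = haplotypes.OUTLIER_BP
    heavy_loss_bp: int = aln_mod.HEAVY_LOSS_BP
    thresholds: filters.FilterThresholds = field(
        default_factory=filters.FilterThresholds
    )
    magnify_path: Optional[PathLike] = None
    gene_table_path: Optional[PathLike] = None
    species_map_path: Optional[PathLike] = None
    #: set True only after manually reviewing flagged studies
    acknowledge_unique_studies: bool = False
    mutation_rate: Optional[float] = None  # substitutions/site/year
    chain_length: int = 10_000_000
    log_every: int = 1000
    skyline_groups: int = 5
    substitution_model: str = "HKY"
    write_plots: bool = False

    @classmethod
    def from_yaml(cls, path: PathLike) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = filters.FilterThresholds(**raw["thresholds"])
        return cls(**raw)


@dataclass
class SpeciesResult:
    species: str
    alignment: aln_mod.Alignment
    haplotype_table: haplotypes.HaplotypeTable
    network: haplotypes.HaplotypeNetwork
    summary: filters.SpeciesSummary
    removed_outliers: list[str]
    flagged_studies: list[str]
    clade_sizes: list[int]


@dataclass
class PipelineResult:
    record_set: RecordSet
    species: dict[str, SpeciesResult]
    retained: list[filters.SpeciesSummary]
    dropped: list[tuple[filters.SpeciesSummary, list[str]]]
    report_lines: list[str]
    report_path: Optional[Path] = None

    @property
    def report(self) -> str:
        return "\n".join(self.report_lines) + "\n"


def _species_safe(name: str) -> str:
    return name.replace(" ", "_")


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage; see the module docstring for the order."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines: list[str] = ["# mtharvest pipeline report"]

    def stage(name: str, before: int, after: int, extra: str = "") -> None:
        suffix = f" ({extra})" if extra else ""
        lines.append(f"{name}: {before} -> {after}{suffix}")

    # 1. parse + dedup
    rs = records_io.parse_genbank_records(cfg.genbank_path)
    stage("parse_genbank_records", rs.provenance_log[0][1], len(rs))
    n0 = len(rs)
    rs = records_io.remove_refseq_duplicates(rs)
    stage("remove_refseq_duplicates", n0, len(rs))

    # 2. standardise
    items = records_io.scrape_feature_items(rs)
    lines.append(f"scrape_feature_items: {len(items)} items from {len(rs)} accessions")
    gene_table = (
        standardise.GeneConversionTable.from_csv(cfg.gene_table_path)
        if cfg.gene_table_path
        else standardise.GeneConversionTable.default()
    )
    items, gene_report = standardise.standardise_gene_names(items, gene_table)
    lines.append(
        f"standardise_gene_names: {gene_report.n_changed} renamed, "
        f"{len(gene_report.unmatched)} unmatched"
    )
    name_map = (
        standardise.SpeciesNameMap.from_csv(cfg.species_map_path)
        if cfg.species_map_path
        else standardise.SpeciesNameMap()
    )
    rs, spp_report = standardise.standardise_spp_names(rs, name_map)
    lines.append(
        f"standardise_spp_names: {spp_report.n_changed} renamed, "
        f"{len(spp_report.flagged_for_review)} flagged for review"
    )

    # 3. gene filter + length filter
    n0 = len(rs)
    rs, items = standardise.gene_of_interest(rs, items, cfg.gene, table=gene_table)
    stage(f"gene_of_interest[{cfg.gene}]", n0, len(rs), f"{len(items)} items")
    n0 = len(rs)
    rs = aln_mod.drop_short_sequences(rs, cfg.minbp)
    stage(f"drop_short_sequences[minbp={cfg.minbp}]", n0, len(rs))

    records_io.write_metadata_table(rs, out_dir / "records_metadata.csv")
    records_io.write_fasta(rs, out_dir / "records_raw.fasta")

    magnify = (
        haplotypes.MagnifyTable.from_csv(cfg.magnify_path)
        if cfg.magnify_path
        else None
    )

    # 4. per-species processing
    by_species: dict[str, list] = {}
    for r in rs:
        by_species.setdefault(r.organism, []).append(r)

    species_results: dict[str, SpeciesResult] = {}
    summaries: list[filters.SpeciesSummary] = []
    for species in sorted(by_species):
        recs = by_species[species]
        if len(recs) < 2:
            lines.append(f"[{species}] skipped: fewer than 2 sequences")
            continue
        sub = RecordSet(records=recs)
        sdir = out_dir / _species_safe(species)
        sdir.mkdir(exist_ok=True)

        seqs = {r.accession_id: r.sequence for r in recs}
        aln = aln_mod.align_sequences(seqs)
        aln, length_summary = aln_mod.crop_to_overlap(
            aln, sub, heavy_loss_bp=cfg.heavy_loss_bp
        )
        lines.append(
            f"[{species}] aligned {aln.nrow} sequences; overlap "
            f"{length_summary.overlap_length} bp; "
            f"{len(length_summary.heavily_trimmed)} heavily trimmed"
        )
        aln = aln_mod.remove_ambiguous_columns(aln)
        lines.append(
            f"[{species}] cleaned alignment: {aln.ncol} bp "
            f"({aln.n_ambiguous_removed} columns removed)"
        )
        aln_mod.write_alignment_fasta(aln, sdir / "alignment_clean.fasta")
        if cfg.write_plots:
            aln_mod.plot_length_histogram(length_summary, sdir / "length_histogram.png")

        ht = haplotypes.collapse_haplotypes(aln, sub)
        flagged = haplotypes.flag_unique_only_studies(ht)
        lines.append(
            f"[{species}] {ht.n_haplotypes} haplotypes from {aln.nrow} sequences; "
            f"{len(flagged)} studies flagged as all-unique"
        )
        if flagged:
            covered = set()
            if magnify is not None:
                covered = {
                    a for a in magnify.counts if a in {r.accession_id for r in recs}
                }
            flagged_accs = {
                a
                for h in ht.rows
                for a in h.member_accessions
                if ht.accession_study.get(a) in flagged
            }
            if not cfg.acknowledge_unique_studies and not (
                magnify is not None and flagged_accs <= set(magnify.counts)
            ):
                lines.append(
                    f"[{species}] HALT: studies {', '.join(flagged)} deposited "
                    "only unique haplotypes; supply a magnify table or set "
                    "acknowledge_unique_studies after manual review"
                )
                raise PipelineHalt(
                    "flag_unique_only_studies",
                    f"{species}: unreviewed all-unique studies {flagged}",
                    lines,
                )
            del covered
        if magnify is not None:
            species_accs = {r.accession_id for r in recs}
            sub_mag = haplotypes.MagnifyTable(
                counts={
                    a: n for a, n in magnify.counts.items() if a in species_accs
                }
            )
            before = ht.total_samples
            ht = haplotypes.magnify_to_sampled_freq(ht, sub_mag)
            if ht.total_samples != before:
                lines.append(
                    f"[{species}] magnified sample total {before} -> "
                    f"{ht.total_samples}"
                )

        net = haplotypes.build_haplotype_network(ht)
        clades = haplotypes.clade_size_summary(net)
        ht, removed = haplotypes.drop_outliers(
            ht, threshold=cfg.outlier_bp, fasta_path=sdir / "post_outlier.fasta"
        )
        if removed:
            net = haplotypes.build_haplotype_network(ht)
            clades = haplotypes.clade_size_summary(net)
        lines.append(
            f"[{species}] outliers removed: {len(removed)}; clade sizes "
            f"(split > 5 bp): {clades}"
        )
        haplotypes.write_haplotype_table(ht, sdir / "haplotypes.csv")
        haplotypes.write_network_edgelist(net, sdir / "network_edges.csv")
        if cfg.write_plots:
            haplotypes.plot_network(net, sdir / "network.png")

        summary = filters.summarise_species(species, ht, aln)
        summaries.append(summary)
        species_results[species] = SpeciesResult(
            species=species,
            alignment=aln,
            haplotype_table=ht,
            network=net,
            summary=summary,
            removed_outliers=removed,
            flagged_studies=flagged,
            clade_sizes=clades,
        )

    # 5. information-content filters
    retained, dropped = filters.apply_filters(summaries, cfg.thresholds)
    filters.write_summary_table(summaries, out_dir / "species_summaries.csv")
    lines.append(
        f"apply_filters: retained {len(retained)}/{len(summaries)} species"
    )
    for s, reasons in dropped:
        lines.append(f"  dropped {s.species_name}: {', '.join(reasons)}")

    # 6. BEAST2 XML for retained species
    if cfg.mutation_rate is not None:
        for s in retained:
            sr = species_results[s.species_name]
            bcfg = beast_io.BeastRunConfig(
                mutation_rate=cfg.mutation_rate,
                output_stem=_species_safe(s.species_name),
                chain_length=cfg.chain_length,
                log_every=cfg.log_every,
                skyline_groups=cfg.skyline_groups,
                substitution_model=cfg.substitution_model,
            )
            xml_path = out_dir / _species_safe(s.species_name) / "beast_skyline.xml"
            beast_io.write_xml(sr.alignment, bcfg, xml_path)
            lines.append(f"[{s.species_name}] wrote {xml_path.name}")

    result = PipelineResult(
        record_set=rs,
        species=species_results,
        retained=retained,
        dropped=dropped,
        report_lines=lines,
    )
    report_path = out_dir / "pipeline_report.txt"
    report_path.write_text(result.report)
    result.report_path = report_path
    logger.info("pipeline complete: report at %s", report_path)
    return result
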