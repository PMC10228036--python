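"""End-to-end orchestration: amplicon/pooled/allele-specific runs and the
regions-of-interest WGS mode.

The procedure is identical whether the reference file holds one amplicon,
two alleles, or many pooled amplicons: QC (and, for pairs, overlap merging
with unmerged pairs dropped and counted), assignment of every read to the
best-scoring reference, tallying, and report rendering. WGS mode extracts
each region of interest (plus flanks) from the genome as a reference and
screens reads with a k-mer prefilter before alignment; it never aligns
against the whole genome.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .align import Assignment, Scoring, assign_to_reference
from .formats import (
    Read,
    Reference,
    Region,
    read_bed,
    read_fasta,
    read_fastq,
    reverse_complement,
    write_fastq,
    write_sam,
)
from .preprocess import MergeParams, QcParams, QcReport, merge_pair, qc_reads
from .quantify import (
    Mode,
    SampleSummary,
    Window,
    default_window,
    signature_of,
    tally,
)
from .report import msa_for_top_signatures, render_report

logger = logging.getLogger("ampliquant")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    fastq1: str
    reference_fasta: Optional[str] = None
    out_dir: str = "ampliquant_out"
    fastq2: Optional[str] = None
    cut_sites: dict[str, int] = field(default_factory=dict)
    window_half_width: int = 10
    mode: Mode = "indel"
    top_n: int = 10
    qc: QcParams = field(default_factory=QcParams)
    merge: MergeParams = field(default_factory=MergeParams)
    scoring: Scoring = field(default_factory=Scoring)
    write_sam_output: bool = False
    gzip_merged: bool = False
    write_merged: bool = False
    # WGS mode
    genome_fasta: Optional[str] = None
    regions_bed: Optional[str] = None
    flank: int = 100
    kmer_length: int = 15

    def to_dict(self) -> dict:
        data = asdict(self)
        return data


@dataclass
class RunSummary:
    """Machine-readable account of one run."""

    qc_report: QcReport
    pairs_merged: int
    pairs_unmerged: int
    sample: SampleSummary
    files: list[str]
    config: RunConfig

    def to_dict(self) -> dict:
        per_reference = {}
        for name, ref_summary in self.sample.per_reference.items():
            from .quantify import signature_key

            per_reference[name] = {
                "assigned_reads": ref_summary.assigned_reads,
                "modified_reads": ref_summary.modified_reads,
                "unmodified_reads": ref_summary.unmodified_reads,
                "window": [ref_summary.window.start, ref_summary.window.end],
                "signature_counts": {
                    signature_key(sig): count
                    for sig, count in sorted(
                        ref_summary.signature_counts.items(),
                        key=lambda item: (-item[1], item[0]),
                    )
                },
            }
        return {
            "tool": "ampliquant",
            "version": __version__,
            "qc_report": self.qc_report.to_dict(),
            "pairs_merged": self.pairs_merged,
            "pairs_unmerged": self.pairs_unmerged,
            "reads": {
                "total": self.sample.total_reads,
                "mapped": self.sample.mapped_reads,
                "unmapped": self.sample.unmapped_reads,
                "ambiguous": self.sample.ambiguous_reads,
            },
            "per_reference": per_reference,
            "files": self.files,
            "config": self.config.to_dict(),
        }


def _load_processed_reads(config: RunConfig):
    """QC (+merge for pairs); returns (reads, QcReport, merged, unmerged)."""
    if config.fastq2 is None:
        raw = list(read_fastq(config.fastq1))
        reads, report = qc_reads(raw, config.qc)
        return reads, report, 0, 0
    pairs = list(read_fastq(config.fastq1, paired_with=config.fastq2))
    report = QcReport()
    merged_reads: list[Read] = []
    merged = unmerged = 0
    from .preprocess import filter_read, trim_read

    for r1, r2 in pairs:
        report.reads_in += 2
        out_pair = []
        for read in (r1, r2):
            trimmed = trim_read(read, config.qc)
            report.bases_trimmed += len(read) - len(trimmed)
            reason = filter_read(trimmed, config.qc)
            if reason is None:
                report.reads_out += 1
                out_pair.append(trimmed)
            elif reason == "quality":
                report.reads_dropped_quality += 1
            elif reason == "n_bases":
                report.reads_dropped_n += 1
            else:
                report.reads_dropped_length += 1
        if len(out_pair) != 2:
            continue  # a failed mate drops the pair from merging
        merged_read = merge_pair(out_pair[0], out_pair[1], config.merge)
        if merged_read is None:
            unmerged += 1
        else:
            merged += 1
            merged_reads.append(merged_read)
    report.check()
    return merged_reads, report, merged, unmerged


def _windows_for(references: Sequence[Reference], config: RunConfig) -> dict[str, Window]:
    windows = {}
    for ref in references:
        windows[ref.name] = default_window(ref, half_width=config.window_half_width)
    return windows


def _apply_cut_sites(references: list[Reference], cut_sites: dict[str, int]) -> list[Reference]:
    unknown = set(cut_sites) - {ref.name for ref in references}
    if unknown:
        raise ValueError(f"cut sites given for unknown references: {sorted(unknown)}")
    return [
        Reference(name=ref.name, sequence=ref.sequence, cut_site=cut_sites.get(ref.name))
        for ref in references
    ]


def _quantify_and_report(
    reads: Sequence[Read],
    assignments: Sequence[Assignment],
    references: Sequence[Reference],
    config: RunConfig,
    qc_report: QcReport,
    merged: int,
    unmerged: int,
) -> RunSummary:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    windows = _windows_for(references, config)
    summary = tally(zip(reads, assignments), references, windows, mode=config.mode)
    logger.info(
        "tally: %d total, %d mapped, %d unmapped, %d ambiguous",
        summary.total_reads, summary.mapped_reads,
        summary.unmapped_reads, summary.ambiguous_reads,
    )

    # pick, per reference and signature, the highest-mean-quality read as the
    # display representative (deterministic; ties by read id)
    representatives: dict[str, dict] = {ref.name: {} for ref in references}
    ref_by_name = {ref.name: ref for ref in references}
    for read, assignment in zip(reads, assignments):
        if assignment.status != "mapped":
            continue
        ref = ref_by_name[assignment.reference_name]
        seq = read.sequence
        if assignment.reverse_complemented:
            seq = reverse_complement(seq)
            oriented = Read(id=read.id, sequence=seq, qualities=list(reversed(read.qualities)))
        else:
            oriented = read
        window = windows[ref.name]
        from .quantify import extract_edits

        events = extract_edits(assignment.alignment, oriented.sequence, ref.sequence)
        signature = signature_of(events, window, config.mode)
        current = representatives[ref.name].get(signature)
        candidate = (oriented, assignment.alignment)
        if current is None or (
            (candidate[0].mean_quality, current[0].id) > (current[0].mean_quality, candidate[0].id)
        ):
            representatives[ref.name][signature] = candidate

    msas = {
        ref.name: msa_for_top_signatures(
            ref, summary, representatives[ref.name], n=config.top_n
        )
        for ref in references
    }
    files = [str(p) for p in render_report(summary, msas, out_dir, top_n=config.top_n)]

    qc_path = out_dir / "qc_report.json"
    with open(qc_path, "w", encoding="utf-8") as handle:
        json.dump(qc_report.to_dict(), handle, indent=2)
    files.append(str(qc_path))

    if config.write_sam_output:
        sam_path = out_dir / "alignments.sam"
        records = []
        for read, assignment in zip(reads, assignments):
            if assignment.status == "mapped":
                seq = read.sequence
                quals = read.qualities
                if assignment.reverse_complemented:
                    seq = reverse_complement(seq)
                    quals = list(reversed(quals))
                oriented = Read(id=read.id, sequence=seq, qualities=quals)
                records.append((oriented, assignment.reference_name, assignment.alignment))
            else:
                records.append((read, None, None))
        write_sam(records, references, sam_path)
        files.append(str(sam_path))

    run_summary = RunSummary(
        qc_report=qc_report,
        pairs_merged=merged,
        pairs_unmerged=unmerged,
        sample=summary,
        files=files,
        config=config,
    )
    summary_path = out_dir / "run_summary.json"
    with open(summary_path, "w", encoding="utf-8") as handle:
        json.dump(run_summary.to_dict(), handle, indent=2)
    run_summary.files.append(str(summary_path))
    return run_summary


def run_amplicon(config: RunConfig) -> RunSummary:
    """The universal amplicon / pooled / allele-specific pipeline."""
    if config.reference_fasta is None:
        raise ValueError("amplicon mode requires a reference FASTA")
    references = _apply_cut_sites(read_fasta(config.reference_fasta), config.cut_sites)
    logger.info("loaded %d reference(s)", len(references))
    reads, qc_report, merged, unmerged = _load_processed_reads(config)
    logger.info(
        "QC: %d in, %d out; pairs merged %d, unmerged %d",
        qc_report.reads_in, qc_report.reads_out, merged, unmerged,
    )
    if config.write_merged and config.fastq2 is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        merged_path = out_dir / ("merged.fastq.gz" if config.gzip_merged else "merged.fastq")
        write_fastq(reads, merged_path, compress=config.gzip_merged)
    assignments = [assign_to_reference(read, references, config.scoring) for read in reads]
    return _quantify_and_report(
        reads, assignments, references, config, qc_report, merged, unmerged
    )


def build_kmer_prefilter(regions: Sequence[Reference], k: int) -> set[str]:
    """Membership index over every k-mer (and reverse complement) of every
    region; regions shorter than k contribute nothing (warning)."""
    if k < 8:
        raise ValueError("prefilter k must be >= 8")
    index: set[str] = set()
    for region in regions:
        seq = region.sequence
        if len(seq) < k:
            logger.warning("region %s shorter than k=%d; not indexed", region.name, k)
            continue
        rc = reverse_complement(seq)
        for s in (seq, rc):
            for i in range(len(s) - k + 1):
                index.add(s[i : i + k])
    return index


def prefilter_verdict(read: Read, index: set[str], k: int) -> bool:
    """True ("test") iff the read shares any k-mer with the index."""
    seq = read.sequence
    return any(seq[i : i + k] in index for i in range(len(seq) - k + 1))


def extract_regions(
    genome: dict[str, str], regions: Sequence[Region], flank: int
) -> list[Reference]:
    """Cut each region +/- flank out of the genome as a Reference; BED cut
    sites are shifted into extracted-sequence coordinates."""
    references = []
    for region in regions:
        if region.chrom not in genome:
            raise ValueError(f"BED chromosome {region.chrom!r} absent from the genome FASTA")
        chrom_seq = genome[region.chrom]
        start = region.start - flank
        end = region.end + flank
        if start < 0 or end > len(chrom_seq):
            logger.warning(
                "region %s +/- flank clipped to chromosome bounds", region.name
            )
            start = max(0, start)
            end = min(len(chrom_seq), end)
        cut_site = None
        if region.cut_site is not None:
            cut_site = region.cut_site - start
            if not 0 <= cut_site <= end - start:
                raise ValueError(
                    f"region {region.name!r}: cut site outside the extracted sequence"
                )
        references.append(
            Reference(name=region.name, sequence=chrom_seq[start:end], cut_site=cut_site)
        )
    return references


def run_wgs(config: RunConfig) -> RunSummary:
    """Regions-of-interest mode for genome-scale input.

    Reads sharing no k-mer with any region (or its reverse complement) are
    counted unmapped without ever reaching the aligner.
    """
    if config.genome_fasta is None or config.regions_bed is None:
        raise ValueError("WGS mode requires --genome and --regions")
    genome = {ref.name: ref.sequence for ref in read_fasta(config.genome_fasta)}
    regions = read_bed(config.regions_bed)
    if not regions:
        raise ValueError(f"{config.regions_bed}: no regions found")
    references = extract_regions(genome, regions, config.flank)
    logger.info("extracted %d region(s) from the genome", len(references))
    index = build_kmer_prefilter(references, config.kmer_length)
    reads, qc_report, merged, unmerged = _load_processed_reads(config)
    assignments = []
    skipped = 0
    for read in reads:
        if prefilter_verdict(read, index, config.kmer_length):
            assignments.append(assign_to_reference(read, references, config.scoring))
        else:
            skipped += 1
            assignments.append(Assignment(status="unmapped"))
    logger.info("prefilter skipped %d of %d reads", skipped, len(reads))
    return _quantify_and_report(
        reads, assignments, references, config, qc_report, merged, unmerged
    )


def configure_logging(verbose: bool = True) -> None:
    """Structured per-stage progress to stderr; counts only, never sequences."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
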