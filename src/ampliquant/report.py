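"""Reporting: reference-anchored alignment of top signatures, read-accounting
bar chart, per-position frequency plot, and allele comparison panel.

Because every read is pairwise-aligned to the same reference, a true MSA
heuristic is unnecessary: per-read alignments are projected onto reference
coordinates deterministically. The union of insertion anchors across rows
defines extra columns, sized to the longest insertion at each anchor.

Figures are written in SVG and PNG; every figure has a CSV twin so all
plotted numbers are machine-checkable (the figures are views, the CSVs the
source of truth).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .align import Alignment
from .formats import Read, Reference, write_fasta
from .quantify import (
    SampleSummary,
    Signature,
    position_frequencies,
    read_summary_table,
    signature_key,
    top_signatures,
)

_PALETTE = {
    "deletion": "#d62728",
    "insertion": "#1f77b4",
    "substitution": "#ff7f0e",
    "depth": "#7f7f7f",
}


@dataclass(frozen=True)
class AnchoredMsa:
    """Gapped rows (label, sequence) with the reference as row 0."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        widths = {len(seq) for _, seq in self.rows}
        if len(widths) > 1:
            raise ValueError("anchored MSA rows differ in length")

    @property
    def width(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0


def anchored_msa(
    reference: Reference,
    representatives: Sequence[tuple[Signature, Read, Alignment, str]],
) -> AnchoredMsa:
    """Project representative reads onto reference coordinates.

    ``representatives`` holds (signature, read, alignment, label) tuples; the
    read sequence must be in reference orientation and the alignment
    left-aligned against ``reference``.
    """
    L = len(reference.sequence)
    # width of the insertion block after each anchor (anchor = ref offset of
    # the first base right of the insertion; block rendered before that column)
    insert_width: dict[int, int] = {}
    projections = []
    for signature, read, alignment, label in representatives:
        if alignment.ref_end > L:
            raise ValueError(f"representative {read.id!r} aligned past reference end")
        ref_cols: list[Optional[str]] = [None] * L
        inserts: dict[int, str] = {}
        i, j = 0, alignment.ref_start
        for op, length in alignment.operations:
            if op == "M":
                for k in range(length):
                    ref_cols[j + k] = read.sequence[i + k]
                i += length
                j += length
            elif op == "D":
                for k in range(length):
                    ref_cols[j + k] = "-"
                j += length
            else:
                inserts[j] = read.sequence[i : i + length]
                insert_width[j] = max(insert_width.get(j, 0), length)
                i += length
        projections.append((label, ref_cols, inserts))

    def build_row(ref_cols: Sequence[Optional[str]], inserts: dict[int, str]) -> str:
        parts: list[str] = []
        for j in range(L + 1):
            if j in insert_width:
                block = inserts.get(j, "")
                parts.append(block.ljust(insert_width[j], "-"))
            if j < L:
                col = ref_cols[j]
                parts.append(col if col is not None else "-")
        return "".join(parts)

    ref_row = build_row(list(reference.sequence), {})
    rows = [(reference.name, ref_row)]
    for label, ref_cols, inserts in projections:
        rows.append((label, build_row(ref_cols, inserts)))
    return AnchoredMsa(rows=tuple(rows))


def msa_for_top_signatures(
    reference: Reference,
    summary: SampleSummary,
    reads_by_signature: dict[Signature, tuple[Read, Alignment]],
    n: int = 10,
) -> AnchoredMsa:
    """Anchored MSA of the n best-supported signatures, labelled with the
    signature key and its percentage of assigned reads."""
    table = top_signatures(summary, reference.name, n=n)
    ref_summary = summary.per_reference[reference.name]
    key_to_sig = {signature_key(sig): sig for sig in ref_summary.signature_counts}
    representatives = []
    for _, row in table.iterrows():
        signature = key_to_sig[row["signature"]]
        if signature not in reads_by_signature:
            continue
        read, alignment = reads_by_signature[signature]
        label = f"{row['signature']} {row['percentage']:.1f}%"
        representatives.append((signature, read, alignment, label))
    return anchored_msa(reference, representatives)


def _save_figure(fig, stem: Path) -> list[Path]:
    paths = []
    for ext in ("svg", "png"):
        path = stem.parent / f"{stem.name}.{ext}"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        paths.append(path)
    plt.close(fig)
    return paths


def _plot_msa(msa: AnchoredMsa, title: str, stem: Path) -> list[Path]:
    n_rows = len(msa.rows)
    width = max(msa.width, 1)
    fig, ax = plt.subplots(
        figsize=(max(6.0, width * 0.12), max(1.5, 0.4 * n_rows + 0.8))
    )
    ax.set_xlim(0, width)
    ax.set_ylim(0, n_rows)
    ax.axis("off")
    ax.set_title(title, fontsize=10)
    for r, (label, sequence) in enumerate(msa.rows):
        y = n_rows - r - 0.5
        ax.text(-0.5, y, label, ha="right", va="center", fontsize=7, family="monospace")
        for c, char in enumerate(sequence):
            color = "#999999" if char == "-" else "black"
            ax.text(
                c + 0.5, y, char, ha="center", va="center", fontsize=7,
                family="monospace", color=color,
            )
    return _save_figure(fig, stem)


def _plot_read_counts(table: pd.DataFrame, reference_name: str, stem: Path) -> list[Path]:
    row = table[table["reference"] == reference_name].iloc[0]
    categories = ["total", "mapped", "modified", "unmodified"]
    values = [
        int(row["total_reads"]),
        int(row["mapped_reads"]),
        int(row["modified_reads"]),
        int(row["unmodified_reads"]),
    ]
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.bar(categories, values, color=["#444444", "#1f77b4", "#d62728", "#2ca02c"])
    ax.set_ylabel("reads")
    ax.set_title(f"Read accounting — {reference_name}", fontsize=10)
    for x, v in enumerate(values):
        ax.text(x, v, str(v), ha="center", va="bottom", fontsize=8)
    return _save_figure(fig, stem)


def _plot_position_frequencies(freq: pd.DataFrame, reference_name: str, stem: Path) -> list[Path]:
    fig, ax = plt.subplots(figsize=(7.0, 3.2))
    for kind in ("deletion", "insertion", "substitution"):
        ax.plot(
            freq["position"], freq[f"{kind}_fraction"],
            label=kind, color=_PALETTE[kind], linewidth=1.2,
        )
    ax.set_xlabel("reference position")
    ax.set_ylabel("fraction of covering reads")
    ax.set_ylim(bottom=0)
    ax.legend(fontsize=8)
    ax.set_title(f"Indel frequency along the reference — {reference_name}", fontsize=10)
    return _save_figure(fig, stem)


def _plot_reference_comparison(summary: SampleSummary, stem: Path) -> list[Path]:
    names = list(summary.per_reference)
    modified = [summary.per_reference[n].modified_reads for n in names]
    unmodified = [summary.per_reference[n].unmodified_reads for n in names]
    fig, ax = plt.subplots(figsize=(1.2 + 1.2 * len(names), 3.2))
    x = range(len(names))
    ax.bar(x, modified, label="modified", color="#d62728")
    ax.bar(x, unmodified, bottom=modified, label="unmodified", color="#2ca02c")
    ax.set_xticks(list(x))
    ax.set_xticklabels(names, fontsize=8)
    ax.set_ylabel("assigned reads")
    ax.legend(fontsize=8)
    ax.set_title("Per-reference (allele) comparison", fontsize=10)
    return _save_figure(fig, stem)


def render_report(
    summary: SampleSummary,
    msas: dict[str, AnchoredMsa],
    out_dir,
    top_n: int = 10,
) -> list[Path]:
    """Write the full figure/CSV/FASTA inventory for a sample.

    Per reference: the anchored-alignment figure with its FASTA export, the
    read-accounting bar chart, and the per-position frequency plot — each
    figure in SVG and PNG with a CSV twin. Multi-reference runs additionally
    get a cross-reference comparison panel.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    accounting = read_summary_table(summary)
    for name in summary.per_reference:
        safe = name.replace("/", "_")
        sig_table = top_signatures(summary, name, n=max(top_n, 1))
        sig_csv = out_dir / f"{safe}.indel_types.csv"
        sig_table.to_csv(sig_csv, index=False)
        written.append(sig_csv)

        counts_csv = out_dir / f"{safe}.read_summary.csv"
        accounting[accounting["reference"].isin(["<sample>", name])].to_csv(
            counts_csv, index=False
        )
        written.append(counts_csv)
        written.extend(_plot_read_counts(accounting, name, out_dir / f"{safe}.read_summary"))

        freq = position_frequencies(summary, name)
        freq_csv = out_dir / f"{safe}.position_frequencies.csv"
        freq.to_csv(freq_csv, index=False)
        written.append(freq_csv)
        written.extend(
            _plot_position_frequencies(freq, name, out_dir / f"{safe}.position_frequencies")
        )

        msa = msas.get(name)
        if msa is not None and msa.rows:
            fasta = out_dir / f"{safe}.top_alignments.fasta"
            write_fasta(((label, seq) for label, seq in msa.rows), fasta)
            written.append(fasta)
            written.extend(
                _plot_msa(msa, f"Top signatures — {name}", out_dir / f"{safe}.top_alignments")
            )
    if len(summary.per_reference) > 1:
        comparison = accounting[accounting["reference"] != "<sample>"]
        comparison_csv = out_dir / "reference_comparison.csv"
        comparison.to_csv(comparison_csv, index=False)
        written.append(comparison_csv)
        written.extend(_plot_reference_comparison(summary, out_dir / "reference_comparison"))
    return written
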