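"""Turn alignments into edit events, modified/unmodified calls, indel
signatures, and per-position frequency profiles.

A read's *signature* is the canonical (left-aligned, sorted) set of edit
events it carries; reads are grouped and counted by it. In ``indel`` mode the
signature holds insertions and deletions only — sequencing-error
substitutions would otherwise fragment the table — while ``base_editor`` mode
additionally keeps substitutions inside the quantification window. The window
(around the expected cut site) scopes the modified/unmodified call, not the
signature identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .align import Alignment, Assignment
from .formats import Read, Reference, reverse_complement

Mode = Literal["indel", "base_editor"]

#: textual key for the empty (unedited) signature in tables
WT_KEY = "WT"

#: default half-width of the quantification window around a cut site
DEFAULT_WINDOW_HALF_WIDTH = 10


@dataclass(frozen=True, order=True)
class EditEvent:
    """One insertion/deletion/substitution in reference coordinates.

    ``position`` is the first deleted base (deletion), the substituted base
    (substitution), or the insertion anchor — the count of reference bases to
    the left of the inserted sequence.
    """

    position: int
    kind: str  # deletion | insertion | substitution
    length: int
    sequence: str = ""  # inserted or substituted read bases; empty for deletion

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "insertion", "substitution"):
            raise ValueError(f"bad event kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("event length must be >= 1")

    @property
    def key(self) -> str:
        code = {"deletion": "D", "insertion": "I", "substitution": "S"}[self.kind]
        tail = f":{self.sequence}" if self.sequence else ""
        return f"{self.position}:{code}:{self.length}{tail}"


Signature = tuple[EditEvent, ...]


def signature_key(signature: Signature) -> str:
    """Compact text key, e.g. ``8:D:3`` or ``6:I:2:GG``; ``WT`` if empty."""
    if not signature:
        return WT_KEY
    return ";".join(event.key for event in signature)


@dataclass(frozen=True)
class Window:
    """Reference interval (0-based half-open) scoping the modified call."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad window [{self.start}, {self.end})")


def default_window(reference: Reference, half_width: int = DEFAULT_WINDOW_HALF_WIDTH) -> Window:
    """Window around the cut site (+/- half_width), or the whole reference
    when no cut site is given."""
    length = len(reference.sequence)
    if reference.cut_site is None:
        return Window(0, length)
    c = reference.cut_site
    return Window(max(0, c - half_width), max(1, min(length, c + half_width)))


def extract_edits(alignment: Alignment, read_seq: str, ref_seq: str) -> list[EditEvent]:
    """Transcribe a left-aligned alignment into events in reference order.

    Each D run yields one deletion, each I run one insertion carrying the
    inserted bases; every mismatched M column yields a single-base
    substitution (adjacent mismatches are not merged — per-position profiles
    and base-editor reporting need single-base resolution). An N read base is
    never a substitution.
    """
    events: list[EditEvent] = []
    i, j = 0, alignment.ref_start
    for op, length in alignment.operations:
        if op == "M":
            for k in range(length):
                rb = read_seq[i + k]
                if rb != "N" and rb != ref_seq[j + k]:
                    events.append(
                        EditEvent(position=j + k, kind="substitution", length=1, sequence=rb)
                    )
            i += length
            j += length
        elif op == "I":
            events.append(
                EditEvent(
                    position=j, kind="insertion", length=length, sequence=read_seq[i : i + length]
                )
            )
            i += length
        else:
            events.append(EditEvent(position=j, kind="deletion", length=length))
            j += length
    return sorted(events)


def classify_read(events: Sequence[EditEvent], window: Window, mode: Mode = "indel") -> bool:
    """True (modified) iff a qualifying event touches the window.

    A deletion qualifies when its footprint intersects the window; an
    insertion when its anchor lies in [start, end] (insertions live between
    bases, so the window's right edge is inclusive for anchors).
    Substitutions qualify only in base_editor mode, at positions inside the
    window.
    """
    for event in events:
        if event.kind == "deletion":
            if event.position < window.end and event.position + event.length > window.start:
                return True
        elif event.kind == "insertion":
            if window.start <= event.position <= window.end:
                return True
        elif mode == "base_editor":
            if window.start <= event.position < window.end:
                return True
    return False


def signature_of(events: Sequence[EditEvent], window: Window, mode: Mode = "indel") -> Signature:
    """Canonical signature: all indels; plus, in base_editor mode, the
    substitutions inside the window."""
    kept = [e for e in events if e.kind in ("insertion", "deletion")]
    if mode == "base_editor":
        kept.extend(
            e
            for e in events
            if e.kind == "substitution" and window.start <= e.position < window.end
        )
    return tuple(sorted(kept))


@dataclass
class ReferenceSummary:
    """Per-reference counts and per-position profile arrays."""

    reference: Reference
    window: Window
    assigned_reads: int = 0
    modified_reads: int = 0
    unmodified_reads: int = 0
    signature_counts: dict[Signature, int] = field(default_factory=dict)
    depth: np.ndarray = None  # type: ignore[assignment]
    deletion_counts: np.ndarray = None  # type: ignore[assignment]
    insertion_counts: np.ndarray = None  # type: ignore[assignment]
    substitution_counts: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        length = len(self.reference.sequence)
        for name in ("depth", "deletion_counts", "insertion_counts", "substitution_counts"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(length, dtype=np.int64))


@dataclass
class SampleSummary:
    """Sample-level read accounting plus per-reference summaries.

    Invariants (asserted by :meth:`check`): total = mapped + unmapped +
    ambiguous; per reference, modified + unmodified = assigned reads =
    sum of signature counts.
    """

    total_reads: int = 0
    mapped_reads: int = 0
    unmapped_reads: int = 0
    ambiguous_reads: int = 0
    per_reference: dict[str, ReferenceSummary] = field(default_factory=dict)

    def check(self) -> None:
        assert self.total_reads == self.mapped_reads + self.unmapped_reads + self.ambiguous_reads
        assert sum(r.assigned_reads for r in self.per_reference.values()) == self.mapped_reads
        for ref_summary in self.per_reference.values():
            assert (
                ref_summary.modified_reads + ref_summary.unmodified_reads
                == ref_summary.assigned_reads
            )
            assert sum(ref_summary.signature_counts.values()) == ref_summary.assigned_reads
            assert (ref_summary.deletion_counts <= ref_summary.depth).all()
            assert (ref_summary.substitution_counts <= ref_summary.depth).all()


def tally(
    assignments: Iterable[tuple[Read, Assignment]],
    references: Sequence[Reference],
    windows: Optional[dict[str, Window]] = None,
    mode: Mode = "indel",
) -> SampleSummary:
    """Single-pass accumulation of a sample summary from read assignments.

    Per-position depth counts every read whose alignment covers the position
    with an M or D column; deletion counts cover every deleted position,
    insertions attach to their anchor, substitutions to their base.
    """
    ref_by_name = {ref.name: ref for ref in references}
    if windows is None:
        windows = {ref.name: default_window(ref) for ref in references}
    summary = SampleSummary()
    for ref in references:
        summary.per_reference[ref.name] = ReferenceSummary(
            reference=ref, window=windows[ref.name]
        )
    for read, assignment in assignments:
        summary.total_reads += 1
        if assignment.status == "unmapped":
            summary.unmapped_reads += 1
            continue
        if assignment.status == "ambiguous":
            summary.ambiguous_reads += 1
            continue
        summary.mapped_reads += 1
        ref = ref_by_name[assignment.reference_name]
        ref_summary = summary.per_reference[ref.name]
        ref_summary.assigned_reads += 1
        alignment = assignment.alignment
        read_seq = read.sequence
        if assignment.reverse_complemented:
            read_seq = reverse_complement(read_seq)
        events = extract_edits(alignment, read_seq, ref.sequence)
        window = ref_summary.window
        if classify_read(events, window, mode):
            ref_summary.modified_reads += 1
        else:
            ref_summary.unmodified_reads += 1
        signature = signature_of(events, window, mode)
        ref_summary.signature_counts[signature] = (
            ref_summary.signature_counts.get(signature, 0) + 1
        )
        # per-position profile
        j = alignment.ref_start
        for op, length in alignment.operations:
            if op in ("M", "D"):
                ref_summary.depth[j : j + length] += 1
                if op == "D":
                    ref_summary.deletion_counts[j : j + length] += 1
                j += length
        for event in events:
            if event.kind == "insertion" and event.position < len(ref.sequence):
                ref_summary.insertion_counts[event.position] += 1
            elif event.kind == "substitution":
                ref_summary.substitution_counts[event.position] += 1
    summary.check()
    return summary


def position_frequencies(summary: SampleSummary, reference_name: str) -> pd.DataFrame:
    """One row per reference position with indel/substitution counts and
    fractions (fraction = count/depth, 0 where depth is 0)."""
    if reference_name not in summary.per_reference:
        raise KeyError(f"unknown reference {reference_name!r}")
    ref_summary = summary.per_reference[reference_name]
    depth = ref_summary.depth.astype(float)
    safe = np.where(depth > 0, depth, 1.0)

    def frac(counts: np.ndarray) -> np.ndarray:
        return np.where(depth > 0, counts / safe, 0.0)

    return pd.DataFrame(
        {
            "position": np.arange(len(ref_summary.reference.sequence)),
            "depth": ref_summary.depth,
            "deletion_count": ref_summary.deletion_counts,
            "insertion_count": ref_summary.insertion_counts,
            "substitution_count": ref_summary.substitution_counts,
            "deletion_fraction": frac(ref_summary.deletion_counts),
            "insertion_fraction": frac(ref_summary.insertion_counts),
            "substitution_fraction": frac(ref_summary.substitution_counts),
        }
    )


def top_signatures(summary: SampleSummary, reference_name: str, n: int = 10) -> pd.DataFrame:
    """The n best-supported signatures for a reference, sorted by read count
    (ties by canonical signature order); percentages are relative to reads
    assigned to the reference. The empty signature participates like any
    other."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if reference_name not in summary.per_reference:
        raise KeyError(f"unknown reference {reference_name!r}")
    ref_summary = summary.per_reference[reference_name]
    assigned = ref_summary.assigned_reads
    rows = sorted(
        ref_summary.signature_counts.items(), key=lambda item: (-item[1], item[0])
    )[:n]
    return pd.DataFrame(
        {
            "signature": [signature_key(sig) for sig, _ in rows],
            "read_count": [count for _, count in rows],
            "percentage": [100.0 * count / assigned if assigned else 0.0 for _, count in rows],
        }
    )


def read_summary_table(summary: SampleSummary) -> pd.DataFrame:
    """The read-accounting quantities (total/mapped/modified/unmodified) as a
    tidy table, one row per reference plus one sample-level row."""
    rows = [
        {
            "reference": "<sample>",
            "total_reads": summary.total_reads,
            "mapped_reads": summary.mapped_reads,
            "unmapped_reads": summary.unmapped_reads,
            "ambiguous_reads": summary.ambiguous_reads,
            "modified_reads": sum(r.modified_reads for r in summary.per_reference.values()),
            "unmodified_reads": sum(r.unmodified_reads for r in summary.per_reference.values()),
        }
    ]
    for name, ref_summary in summary.per_reference.items():
        rows.append(
            {
                "reference": name,
                "total_reads": summary.total_reads,
                "mapped_reads": ref_summary.assigned_reads,
                "unmapped_reads": summary.unmapped_reads,
                "ambiguous_reads": summary.ambiguous_reads,
                "modified_reads": ref_summary.modified_reads,
                "unmodified_reads": ref_summary.unmodified_reads,
            }
        )
    return pd.DataFrame(rows)
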