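"""Read quality control and paired-end overlap merging.

The trimmer and filters mirror fastp's documented defaults (sliding window
Q20, qualified base Q15, at most 40% unqualified bases, at most 5 Ns, minimum
length 15); the merger mirrors FLASH's (minimum overlap 10, maximum mismatch
density 0.25). Both are deterministic re-implementations of those contracts,
not byte-compatible ports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from .formats import MAX_QUALITY, Read, reverse_complement

FilterReason = Literal["quality", "n_bases", "length"]


@dataclass(frozen=True)
class QcParams:
    """Trimming and filtering thresholds (Phred scale, base counts)."""

    window_size: int = 4
    window_quality: int = 20
    qualified_quality: int = 15
    max_unqualified_fraction: float = 0.40
    max_n_bases: int = 5
    min_length: int = 15

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if min(self.window_quality, self.qualified_quality, self.max_n_bases, self.min_length) < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0.0 <= self.max_unqualified_fraction <= 1.0:
            raise ValueError("max_unqualified_fraction must lie in [0, 1]")


@dataclass
class QcReport:
    """Read-accounting totals for one QC pass; counts are conserved."""

    reads_in: int = 0
    reads_out: int = 0
    reads_dropped_quality: int = 0
    reads_dropped_n: int = 0
    reads_dropped_length: int = 0
    bases_trimmed: int = 0

    def check(self) -> None:
        dropped = (
            self.reads_dropped_quality + self.reads_dropped_n + self.reads_dropped_length
        )
        assert self.reads_in == self.reads_out + dropped, "QC read accounting broken"
        assert min(
            self.reads_in,
            self.reads_out,
            self.reads_dropped_quality,
            self.reads_dropped_n,
            self.reads_dropped_length,
            self.bases_trimmed,
        ) >= 0

    def to_dict(self) -> dict:
        return {
            "reads_in": self.reads_in,
            "reads_out": self.reads_out,
            "reads_dropped_quality": self.reads_dropped_quality,
            "reads_dropped_n": self.reads_dropped_n,
            "reads_dropped_length": self.reads_dropped_length,
            "bases_trimmed": self.bases_trimmed,
        }


@dataclass(frozen=True)
class MergeParams:
    min_overlap: int = 10
    max_overlap_mismatch_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0.0 <= self.max_overlap_mismatch_fraction <= 1.0:
            raise ValueError("max_overlap_mismatch_fraction must lie in [0, 1]")


def trim_read(read: Read, params: QcParams) -> Read:
    """Trim the low-quality 3' tail of a read.

    The kept prefix ends at the last position whose trailing window (the up to
    ``window_size`` bases ending at it) has mean quality >= ``window_quality``
    and whose own quality meets that threshold too. Because the criterion at a
    position only looks left of it, trimming is idempotent.
    """
    quals = read.qualities
    w, threshold = params.window_size, params.window_quality
    keep = 0
    window_sum = 0
    for p in range(len(quals)):
        window_sum += quals[p]
        if p >= w:
            window_sum -= quals[p - w]
        window_len = min(w, p + 1)
        if quals[p] >= threshold and window_sum / window_len >= threshold:
            keep = p + 1
    if keep == len(quals):
        return read
    return Read(id=read.id, sequence=read.sequence[:keep], qualities=quals[:keep])


def filter_read(read: Read, params: QcParams) -> Optional[FilterReason]:
    """Return None if the (already trimmed) read passes, else the first
    failing check among length, n_bases, quality — in that order."""
    n = len(read)
    if n < params.min_length:
        return "length"
    if read.sequence.count("N") > params.max_n_bases:
        return "n_bases"
    unqualified = sum(1 for q in read.qualities if q < params.qualified_quality)
    if unqualified / n > params.max_unqualified_fraction:
        return "quality"
    return None


@dataclass(frozen=True)
class _OverlapCandidate:
    length: int
    mismatch_fraction: float


def merge_pair(r1: Read, r2: Read, params: MergeParams) -> Optional[Read]:
    """Merge an "innie" read pair by exhaustive overlap search.

    ``r2`` is reverse-complemented (qualities reversed); every overlap length
    ``o`` from ``min_overlap`` up to the shorter read is scored by mismatch
    fraction over the overlap (N counts as a match). The candidate with the
    lowest fraction wins, ties going to the longer overlap. Per overlap
    column: agreeing bases keep quality ``min(60, max(q1, q2))``; disagreeing
    columns keep the higher-quality base with quality ``|q1 - q2|`` (the r1
    base on a quality tie). Returns None when no overlap qualifies.
    """
    seq2 = reverse_complement(r2.sequence)
    qual2 = list(reversed(r2.qualities))
    n1, n2 = len(r1), len(r2)
    best: Optional[_OverlapCandidate] = None
    for o in range(params.min_overlap, min(n1, n2) + 1):
        tail = r1.sequence[n1 - o :]
        head = seq2[:o]
        mismatches = sum(
            1 for a, b in zip(tail, head) if a != b and a != "N" and b != "N"
        )
        fraction = mismatches / o
        if fraction > params.max_overlap_mismatch_fraction:
            continue
        if best is None or fraction < best.mismatch_fraction or (
            fraction == best.mismatch_fraction and o > best.length
        ):
            best = _OverlapCandidate(length=o, mismatch_fraction=fraction)
    if best is None:
        return None
    o = best.length
    merged_seq = list(r1.sequence[: n1 - o])
    merged_qual = list(r1.qualities[: n1 - o])
    for k in range(o):
        b1, q1 = r1.sequence[n1 - o + k], r1.qualities[n1 - o + k]
        b2, q2 = seq2[k], qual2[k]
        if b1 == b2:
            merged_seq.append(b1)
            merged_qual.append(min(MAX_QUALITY, max(q1, q2)))
        elif b1 == "N":
            merged_seq.append(b2)
            merged_qual.append(q2)
        elif b2 == "N":
            merged_seq.append(b1)
            merged_qual.append(q1)
        elif q2 > q1:
            merged_seq.append(b2)
            merged_qual.append(q2 - q1)
        else:
            merged_seq.append(b1)
            merged_qual.append(q1 - q2)
    merged_seq.extend(seq2[o:])
    merged_qual.extend(qual2[o:])
    return Read(id=r1.id, sequence="".join(merged_seq), qualities=merged_qual)


def qc_reads(reads, params: QcParams):
    """Trim + filter a read iterable; returns (passing reads, QcReport)."""
    report = QcReport()
    passed: list[Read] = []
    for read in reads:
        report.reads_in += 1
        trimmed = trim_read(read, params)
        report.bases_trimmed += len(read) - len(trimmed)
        reason = filter_read(trimmed, params)
        if reason is None:
            report.reads_out += 1
            passed.append(trimmed)
        elif reason == "quality":
            report.reads_dropped_quality += 1
        elif reason == "n_bases":
            report.reads_dropped_n += 1
        else:
            report.reads_dropped_length += 1
    report.check()
    return passed, report
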