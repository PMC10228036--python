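"""Semi-global affine-gap alignment of reads onto amplicon references.

The aligner is global in the read and free at both reference ends: every read
base must be explained, while unaligned reference flanks cost nothing. Gap
cost is affine, ``gap_open + gap_extend * length``. ``N`` in the read matches
any reference base with score 0. Scoring defaults (match 1, mismatch 4, gap
open 6, gap extend 1) mirror the BWA-MEM defaults so mapped/unmapped
behaviour is comparable to a conventional mapping stage.

The dynamic program is a classic three-state (match / insertion-in-read /
deletion-from-reference) recurrence, jitted with numba when available. The
traceback is deterministic: at every cell, co-optimal predecessors are broken
in the fixed order M, then D, then I, and indel runs are subsequently
left-aligned so equivalent alignments compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .formats import Read, Reference, reverse_complement

NEG_INF = np.int32(-(10**8))

_BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


class AlignmentError(ValueError):
    """Inconsistent alignment input."""


@dataclass(frozen=True)
class Scoring:
    """Alignment rewards/penalties (all penalties non-negative integers)."""

    match: int = 1
    mismatch: int = 4
    gap_open: int = 6
    gap_extend: int = 1
    #: fraction of the maximum attainable score (match * read length) a read
    #: must reach to be called mapped
    min_mapped_score_fraction: float = 0.30

    def __post_init__(self) -> None:
        if min(self.match, self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("scoring parameters must be >= 0")
        if not 0.0 <= self.min_mapped_score_fraction <= 1.0:
            raise ValueError("min_mapped_score_fraction must lie in [0, 1]")

    def min_mapped_score(self, read_length: int) -> float:
        return self.min_mapped_score_fraction * self.match * read_length


@dataclass(frozen=True)
class Alignment:
    """Placement of a read on a reference with CIGAR-style operations.

    ``operations`` is a run-length list over {M, I, D}; M consumes one read
    and one reference base (match or mismatch), I consumes read only, D
    reference only. The read is wholly consumed (sum of M+I == read length);
    leading/trailing D runs never occur.
    """

    ref_start: int
    score: int
    operations: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for op, length in self.operations:
            if op not in "MID" or length < 1:
                raise AlignmentError(f"bad operation ({op!r}, {length})")
        for (op1, _), (op2, _) in zip(self.operations, self.operations[1:]):
            if op1 == op2:
                raise AlignmentError("adjacent operations share an op code")
        if self.operations and (
            self.operations[0][0] == "D" or self.operations[-1][0] == "D"
        ):
            raise AlignmentError("leading/trailing deletion is not allowed")

    @property
    def read_length(self) -> int:
        return sum(length for op, length in self.operations if op in "MI")

    @property
    def ref_span(self) -> int:
        return sum(length for op, length in self.operations if op in "MD")

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_span


def encode(sequence: str) -> np.ndarray:
    return np.fromiter((_BASE_CODES[b] for b in sequence), dtype=np.int8, count=len(sequence))


def _fill(read, ref, match, mismatch, gap_open, gap_extend):
    """Three-state DP fill. Row 0 of S_M holds 0 (free leading reference gap);
    deletions may not open before the first read base."""
    n, m = read.shape[0], ref.shape[0]
    s_m = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    s_i = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    s_d = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    for j in range(m + 1):
        s_m[0, j] = 0
    oe = gap_open + gap_extend
    for i in range(1, n + 1):
        rb = read[i - 1]
        for j in range(m + 1):
            # insertion in read (vertical)
            best = s_m[i - 1, j] - oe
            if s_d[i - 1, j] - oe > best:
                best = s_d[i - 1, j] - oe
            if s_i[i - 1, j] - gap_extend > best:
                best = s_i[i - 1, j] - gap_extend
            s_i[i, j] = best
            if j == 0:
                continue
            # aligned pair (diagonal)
            sub = 0 if rb == 4 else (match if rb == ref[j - 1] else -mismatch)
            diag = s_m[i - 1, j - 1]
            if s_d[i - 1, j - 1] > diag:
                diag = s_d[i - 1, j - 1]
            if s_i[i - 1, j - 1] > diag:
                diag = s_i[i - 1, j - 1]
            s_m[i, j] = diag + sub
            # deletion from reference (horizontal); not from row 0
            best = s_m[i, j - 1] - oe
            if s_d[i, j - 1] - gap_extend > best:
                best = s_d[i, j - 1] - gap_extend
            if s_i[i, j - 1] - oe > best:
                best = s_i[i, j - 1] - oe
            s_d[i, j] = best
    return s_m, s_i, s_d


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _fill = njit(cache=True)(_fill)
except Exception:  # numba unavailable: plain-Python fill still correct
    pass


_M, _I, _D = 0, 1, 2


def semiglobal_align(read_seq: str, ref_seq: str, scoring: Scoring = Scoring()) -> Alignment:
    """Align a read semi-globally onto a reference; returns a maximal-score
    alignment with deterministic M > D > I tie-breaking."""
    if not read_seq or not ref_seq:
        raise AlignmentError("read and reference must be non-empty")
    read = encode(read_seq)
    ref = encode(ref_seq)
    if np.any(ref == 4):
        raise AlignmentError("reference contains N")
    s_m, s_i, s_d = _fill(
        read, ref, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    n, m = len(read_seq), len(ref_seq)
    # end cell: best of M/I states in the last row (trailing D forbidden),
    # M preferred over I, then smallest reference end
    best_score, best_j, best_state = None, -1, _M
    for j in range(m + 1):
        for state, matrix in ((_M, s_m), (_I, s_i)):
            value = int(matrix[n, j])
            if best_score is None or value > best_score:
                best_score, best_j, best_state = value, j, state
    assert best_score is not None and best_score > int(NEG_INF)

    oe = scoring.gap_open + scoring.gap_extend
    ops_rev: list[str] = []
    i, j, state = n, best_j, best_state
    while i > 0:
        if state == _M:
            rb = read[i - 1]
            sub = 0 if rb == 4 else (
                scoring.match if rb == ref[j - 1] else -scoring.mismatch
            )
            target = int(s_m[i, j]) - sub
            ops_rev.append("M")
            i, j = i - 1, j - 1
            for cand, matrix in ((_M, s_m), (_D, s_d), (_I, s_i)):
                if int(matrix[i, j]) == target:
                    state = cand
                    break
            else:  # pragma: no cover
                raise AssertionError("traceback failed in M state")
        elif state == _D:
            target = int(s_d[i, j])
            ops_rev.append("D")
            j -= 1
            if int(s_m[i, j]) == target + oe:
                state = _M
            elif int(s_d[i, j]) == target + scoring.gap_extend:
                state = _D
            elif int(s_i[i, j]) == target + oe:
                state = _I
            else:  # pragma: no cover
                raise AssertionError("traceback failed in D state")
        else:
            target = int(s_i[i, j])
            ops_rev.append("I")
            i -= 1
            if int(s_m[i, j]) == target + oe:
                state = _M
            elif int(s_d[i, j]) == target + oe:
                state = _D
            elif int(s_i[i, j]) == target + scoring.gap_extend:
                state = _I
            else:  # pragma: no cover
                raise AssertionError("traceback failed in I state")
    ref_start = j
    operations = _run_length(reversed(ops_rev))
    return Alignment(ref_start=ref_start, score=best_score, operations=operations)


def _run_length(ops) -> tuple[tuple[str, int], ...]:
    runs: list[tuple[str, int]] = []
    for op in ops:
        if runs and runs[-1][0] == op:
            runs[-1] = (op, runs[-1][1] + 1)
        else:
            runs.append((op, 1))
    return tuple(runs)


def _score_of(operations, ref_start: int, read_seq: str, ref_seq: str, scoring: Scoring) -> int:
    score, i, j = 0, 0, ref_start
    for op, length in operations:
        if op == "M":
            for k in range(length):
                rb = read_seq[i + k]
                if rb == "N":
                    pass
                elif rb == ref_seq[j + k]:
                    score += scoring.match
                else:
                    score -= scoring.mismatch
            i += length
            j += length
        elif op == "I":
            score -= scoring.gap_open + scoring.gap_extend * length
            i += length
        else:
            score -= scoring.gap_open + scoring.gap_extend * length
            j += length
    return score


def _check_consistent(alignment: Alignment, read_seq: str, ref_seq: str) -> None:
    if alignment.read_length != len(read_seq):
        raise AlignmentError(
            f"alignment consumes {alignment.read_length} read bases, read has {len(read_seq)}"
        )
    if alignment.ref_end > len(ref_seq):
        raise AlignmentError("alignment runs past the reference end")


def left_align_indels(
    alignment: Alignment,
    read_seq: str,
    ref_seq: str,
    scoring: Scoring = Scoring(),
) -> Alignment:
    """Shift every indel run to its smallest equivalent reference coordinate.

    A one-base left shift of a run is taken when the column it re-pairs on the
    right is identical in content to the column it consumes on the left, or
    turns a mismatch column into a match (so the placement still reproduces
    the read with no new substitution). The score is recomputed afterwards;
    the implied read never changes and the operation is idempotent.
    """
    _check_consistent(alignment, read_seq, ref_seq)
    ops = [list(run) for run in alignment.operations]
    ref_start = alignment.ref_start

    changed = True
    while changed:
        changed = False
        # running read/ref offsets at the start of each run
        i = 0
        j = ref_start
        positions = []
        for op, length in ops:
            positions.append((i, j))
            if op == "M":
                i += length
                j += length
            elif op == "I":
                i += length
            else:
                j += length
        for idx, (op, length) in enumerate(ops):
            if op == "M" or idx == 0:
                continue
            prev_op, prev_len = ops[idx - 1]
            if prev_op != "M" or prev_len < 1:
                continue
            i0, j0 = positions[idx]
            if op == "D":
                left_ref = ref_seq[j0 - 1]
                right_ref = ref_seq[j0 + length - 1]
                read_base = read_seq[i0 - 1]
                allowed = right_ref == left_ref or right_ref == read_base
            else:
                left_read = read_seq[i0 - 1]
                right_read = read_seq[i0 + length - 1]
                ref_base = ref_seq[j0 - 1]
                allowed = right_read == left_read or right_read == ref_base
            if not allowed:
                continue
            if prev_len == 1:
                before = ops[idx - 2] if idx >= 2 else None
                if op == "D" and before is None:
                    continue  # would create a leading deletion
                if before is not None and before[0] == op:
                    continue  # would merge two distinct indel runs
            # take the step: shrink previous M, grow/create following M
            ops[idx - 1][1] -= 1
            if idx + 1 < len(ops) and ops[idx + 1][0] == "M":
                ops[idx + 1][1] += 1
            else:
                ops.insert(idx + 1, ["M", 1])
            if ops[idx - 1][1] == 0:
                del ops[idx - 1]
            changed = True
            break

    # strip degenerate leading insertion bookkeeping: ops may now start with I
    merged: list[list] = []
    for op, length in ops:
        if merged and merged[-1][0] == op:
            merged[-1][1] += length
        else:
            merged.append([op, length])
    operations = tuple((op, length) for op, length in merged)
    score = _score_of(operations, ref_start, read_seq, ref_seq, scoring)
    return Alignment(ref_start=ref_start, score=score, operations=operations)


@dataclass(frozen=True)
class Assignment:
    """Outcome of placing one read against a reference set."""

    status: str  # mapped | unmapped | ambiguous
    reference_name: Optional[str] = None
    alignment: Optional[Alignment] = None
    reverse_complemented: bool = False

    def __post_init__(self) -> None:
        if self.status not in ("mapped", "unmapped", "ambiguous"):
            raise ValueError(f"bad status {self.status!r}")
        has_fields = self.reference_name is not None and self.alignment is not None
        if (self.status == "mapped") != has_fields:
            raise ValueError("reference_name/alignment present iff status is mapped")


def assign_to_reference(
    read: Read, references: Sequence[Reference], scoring: Scoring = Scoring()
) -> Assignment:
    """Assign a read to the best-scoring reference.

    The forward orientation is tried against every reference; only when the
    best forward score misses the mapped threshold is the reverse complement
    tried (merged amplicon reads have known orientation, so this halves work
    in the common case). Ties between references at the best score yield
    status ``ambiguous``.
    """
    if not references:
        raise ValueError("assign_to_reference requires at least one reference")
    if len(read) == 0:
        return Assignment(status="unmapped")
    threshold = scoring.min_mapped_score(len(read))

    def best_against(sequence: str):
        scored = [
            (semiglobal_align(sequence, ref.sequence, scoring), ref) for ref in references
        ]
        best = max(a.score for a, _ in scored)
        winners = [(a, ref) for a, ref in scored if a.score == best]
        return best, winners

    query = read.sequence
    revcomp = False
    best, winners = best_against(query)
    if best < threshold:
        rc_query = reverse_complement(query)
        rc_best, rc_winners = best_against(rc_query)
        if rc_best > best:
            best, winners, query, revcomp = rc_best, rc_winners, rc_query, True
    if best < threshold:
        return Assignment(status="unmapped")
    if len(winners) > 1:
        return Assignment(status="ambiguous")
    alignment, ref = winners[0]
    aligned = left_align_indels(alignment, query, ref.sequence, scoring)
    return Assignment(
        status="mapped",
        reference_name=ref.name,
        alignment=aligned,
        reverse_complemented=revcomp,
    )
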