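"""Independent brute-force affine-gap DP oracle used only by tests.

Plain-Python three-matrix recurrence, written without reference to the
package's aligner: global in the read, free reference end gaps, affine gap
cost ``open + extend * length``, N in the read scoring 0 against anything.
Score only — the implementation under test must additionally reconstruct the
read from its own CIGAR.
"""

from __future__ import annotations

NEG = float("-inf")


def oracle_score(
    read: str,
    ref: str,
    match: int = 1,
    mismatch: int = 4,
    gap_open: int = 6,
    gap_extend: int = 1,
) -> int:
    n, m = len(read), len(ref)
    oe = gap_open + gap_extend
    # state matrices indexed [read prefix][ref prefix]
    mat = [[NEG] * (m + 1) for _ in range(n + 1)]
    ins = [[NEG] * (m + 1) for _ in range(n + 1)]
    dele = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        mat[0][j] = 0.0  # free leading reference gap: start anywhere
    for i in range(1, n + 1):
        for j in range(m + 1):
            ins[i][j] = max(mat[i - 1][j] - oe, ins[i - 1][j] - gap_extend, dele[i - 1][j] - oe)
            if j == 0:
                continue
            if read[i - 1] == "N":
                s = 0
            elif read[i - 1] == ref[j - 1]:
                s = match
            else:
                s = -mismatch
            mat[i][j] = max(mat[i - 1][j - 1], ins[i - 1][j - 1], dele[i - 1][j - 1]) + s
            dele[i][j] = max(mat[i][j - 1] - oe, dele[i][j - 1] - gap_extend, ins[i][j - 1] - oe)
    # trailing deletions are never part of the alignment; reference overhang free
    return int(max(max(mat[n][j], ins[n][j]) for j in range(m + 1)))


def implied_read(operations, ref_start: int, read: str, ref: str) -> str:
    """Reconstruct the read from the alignment operations (M columns take the
    read's own bases, so this checks length accounting and span only)."""
    out = []
    i, j = 0, ref_start
    for op, length in operations:
        if op == "M":
            out.append(read[i : i + length])
            if j + length > len(ref):
                raise AssertionError("M run leaves the reference")
            i += length
            j += length
        elif op == "I":
            out.append(read[i : i + length])
            i += length
        elif op == "D":
            if j + length > len(ref):
                raise AssertionError("D run leaves the reference")
            j += length
        else:
            raise AssertionError(f"unknown op {op}")
    if i != len(read):
        raise AssertionError("operations do not consume the whole read")
    return "".join(out)


def random_instance(rng, max_ref_len: int = 40, max_edits: int = 3):
    """A random reference and a read derived from it by up to ``max_edits``
    random substitutions/insertions/deletions."""
    bases = "ACGT"
    ref_len = rng.integers(10, max_ref_len + 1)
    ref = "".join(bases[rng.integers(0, 4)] for _ in range(ref_len))
    read = list(ref)
    for _ in range(rng.integers(0, max_edits + 1)):
        if not read:
            break
        kind = rng.integers(0, 3)
        pos = int(rng.integers(0, len(read)))
        if kind == 0:  # substitution
            read[pos] = bases[rng.integers(0, 4)]
        elif kind == 1:  # deletion of 1-3 bases
            del read[pos : pos + int(rng.integers(1, 4))]
        else:  # insertion of 1-3 bases
            insert = "".join(bases[rng.integers(0, 4)] for _ in range(rng.integers(1, 4)))
            read[pos:pos] = list(insert)
    if not read:
        read = [bases[rng.integers(0, 4)]]
    return "".join(read), ref
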