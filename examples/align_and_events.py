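"""Align single reads to an amplicon and inspect their edit events.

Shows the semi-global affine-gap aligner on three reads — exact, deleted,
inserted — and how CIGAR-style operations become canonical edit events.
"""

from ampliquant import (
    Reference,
    extract_edits,
    left_align_indels,
    semiglobal_align,
    signature_key,
    signature_of,
)
from ampliquant.quantify import Window

reference = Reference(name="amp", sequence="ACGGTCATTGCAAGGCTTAA")

reads = {
    "exact": reference.sequence,
    "3bp deletion": reference.sequence[:8] + reference.sequence[11:],
    "GG insertion": reference.sequence[:6] + "GG" + reference.sequence[6:],
}

window = Window(0, len(reference.sequence))
for label, read_seq in reads.items():
    aln = semiglobal_align(read_seq, reference.sequence)
    aln = left_align_indels(aln, read_seq, reference.sequence)
    events = extract_edits(aln, read_seq, reference.sequence)
    cigar = "".join(f"{length}{op}" for op, length in aln.operations)
    key = signature_key(signature_of(events, window))
    print(f"{label:14s} score={aln.score:3d}  CIGAR={cigar:12s}  signature={key}")

print()
print("The score is matches minus mismatch (4) and affine gap (6 + 1/base)")
print("penalties; the signature is the canonical left-aligned indel set.")
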