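"""Merge an overlapping read pair back into its sequenced fragment.

A 180-base fragment sequenced as 2 x 100-base reads overlaps by 20 bases;
the merger reverse-complements read 2, scans all overlap lengths and
reconstructs the fragment, taking the higher-quality base wherever the
mates disagree.
"""

import numpy as np

from ampliquant import MergeParams, Read, merge_pair
from ampliquant.formats import reverse_complement

rng = np.random.default_rng(4)
fragment = "".join(rng.choice(list("ACGT"), size=180))

r1 = Read(id="pair", sequence=fragment[:100], qualities=[38] * 100)
r2_seq = reverse_complement(fragment[-100:])
r2 = Read(id="pair", sequence=r2_seq, qualities=[30] * 100)

merged = merge_pair(r1, r2, MergeParams())
print(f"fragment length:    {len(fragment)}")
print(f"merged length:      {len(merged)}")
print(f"exact reconstruction: {merged.sequence == fragment}")

# introduce one disagreement in the overlap: read 1 (Q38) should win
bases = list(r2_seq)
pos = 90  # fragment position 89, inside the 20-base overlap
bases[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bases[pos]]
r2_err = Read(id="pair", sequence="".join(bases), qualities=[30] * 100)
merged_err = merge_pair(r1, r2_err, MergeParams())
print(f"with a read-2 error:  {merged_err.sequence == fragment} "
      f"(disagreeing column kept the Q38 base at quality 8)")
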