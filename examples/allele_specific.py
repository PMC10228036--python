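"""Allele-specific analysis: assign reads from a heterozygous locus.

Two 200-base alleles differ at three positions (as in a heterozygous point
mutant). Reads simulated from each allele are assigned to the best-scoring
reference; with distinct alleles every error-free read lands on its source.
"""

import numpy as np

from ampliquant import Reference, SimSpec, assign_to_reference, simulate_reads, tally

rng = np.random.default_rng(9)
seq_wt = "".join(rng.choice(list("ACGT"), size=200))
seq_mut = list(seq_wt)
for pos in (60, 100, 140):
    seq_mut[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq_mut[pos]]
alleles = [
    Reference(name="wild_type", sequence=seq_wt),
    Reference(name="mutant", sequence="".join(seq_mut)),
]

reads, sources = [], []
for allele in alleles:
    spec = SimSpec(reference=allele, spectrum=(), n_reads=300, read_length=200,
                   substitution_error_rate=0.0, seed=11)
    batch, _ = simulate_reads(spec)
    reads.extend(batch)
    sources.extend([allele.name] * len(batch))

assignments = [assign_to_reference(read, alleles) for read in reads]
summary = tally(zip(reads, assignments), alleles)
correct = sum(
    1 for a, src in zip(assignments, sources)
    if a.status == "mapped" and a.reference_name == src
)
print(f"reads:              {summary.total_reads}")
for name in ("wild_type", "mutant"):
    print(f"assigned to {name}: {summary.per_reference[name].assigned_reads}")
print(f"correctly assigned: {correct}/{len(reads)}")
print()
print("Ties between references are reported as 'ambiguous', never guessed,")
print("so allele-specific editing rates are not biased by cross-assignment.")
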