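# Methods

## Problem and pipeline shape

CRISPR/Cas editing at a target locus is assayed by sequencing PCR amplicons
(or whole genomes) and counting the insertion/deletion mutations that
non-homologous end joining leaves at the cut site. The pipeline is the
classical one — quality control, optional paired-end merging, mapping,
variant extraction, counting, plotting — but implemented natively end to
end, with deterministic contracts at every stage, instead of shelling out to
fastp/FLASH/BWA-MEM/samtools equivalents. The procedure is identical whether
the reference FASTA holds one amplicon, two alleles of a heterozygous locus,
or a pool of amplicons; the WGS mode differs only in how references are
obtained (extracted from a genome around BED regions) and in a k-mer
prescreen.

## Read QC

Trimming scans the read once, left to right, and keeps the prefix ending at
the last position whose trailing window (the up-to-`window_size` bases
ending at it, default 4) has mean quality ≥ `window_quality` (default Q20)
and whose own quality also meets that threshold. Because the decision at a
position depends only on bases at or before it, trimming is idempotent by
construction. The per-base condition is deliberate: it guarantees the kept
read never ends in a base below the window threshold, at the cost of
occasionally trimming a low-quality base whose window average is good.
Filtering then applies three ordered checks — length ≥ 15, ≤ 5 N bases,
≤ 40% of bases below Q15 — reporting the first failure; the defaults mirror
fastp's documented defaults since amplicon pipelines conventionally start
there. Adapter trimming is out of scope: amplicon reads are primer-defined.

The QC report is conserved by construction (`reads_in == reads_out +` the
three drop counters) and asserted on every run.

## Paired-end merging

Read 2 is reverse-complemented (qualities reversed) and every "innie"
overlap length from `min_overlap` (10) to the shorter read length is scored
by mismatch density over the overlap; N counts as a match. Candidates with
density ≤ 0.25 compete; lowest density wins, ties to the longer overlap.
Consensus per overlap column: agreement keeps the base at quality
`min(60, max(q1, q2))`; disagreement keeps the higher-quality base at
quality `|q1 − q2|` (read 1 on a tie); a column where one base is N keeps
the other base at its own quality (halving a good base's quality against an
uninformative N would discard real evidence). "Outie" overlaps
(read-through of fragments shorter than the read) are not merged — rare for
designed amplicons — and unmerged pairs are dropped from quantification but
counted in the run summary, since analysing the mates separately would
double-count fragments.

## Alignment

The aligner is a three-state (match / insertion-in-read / deletion-from-
reference) affine-gap dynamic program, global in the read with free leading
and trailing reference gaps: every read base must be explained, reference
overhang costs nothing, and alignments never begin or end with a deletion.
Scoring defaults (match +1, mismatch −4, gap open −6, gap extend −1 per
base, so a length-ℓ gap costs 6+ℓ) mirror BWA-MEM's so mapped/unmapped
behaviour is comparable to the conventional mapping stage; N in the read
scores 0 against anything. The fill is numba-jitted (falling back to the
same plain-Python loops when numba is unavailable); exact DP was chosen over
seeded heuristics because amplicon references are short — a 200×200 problem
is microseconds — and the WGS mode regains throughput through the k-mer
prescreen rather than through alignment shortcuts.

Determinism: the traceback resolves co-optimal predecessors in the fixed
order M, then D, then I at every cell, and the end cell prefers the M state
and the smallest reference end among ties. Any fixed rule would do, because
indel placement is subsequently canonicalized.

**Left-alignment.** Each indel run is shifted one base at a time toward
smaller reference coordinates. A step is taken when the column it re-pairs
is identical in content to the column it consumes — the standard
homopolymer/microsatellite shift — or when the re-paired column turns a
mismatch into a match, which removes a spurious substitution event next to
the indel (the placement then reproduces the read with strictly fewer
events). Steps that would create a new mismatch, merge two distinct indel
runs, or leave a leading deletion are refused. The loop runs to a fixed
point, so the operation is idempotent; the score is recomputed afterwards
(it can only improve, and only in the mismatch-removal case).

**Multi-reference assignment.** A read is aligned to every reference; the
best score wins. If the best forward score misses the mapped threshold
(0.30 × match × read length — a documented, deterministic stand-in for a
mapping-quality rule), the reverse complement is tried and the better
orientation kept; merged amplicon reads have a known orientation, so the
common case does half the work. Two or more references tying at the best
score make the read *ambiguous*: it is excluded from per-reference counts
but tallied, because assigning ties arbitrarily would bias allele-specific
results.

## Quantification

Edit events are transcribed directly from the left-aligned operations: one
deletion per D run, one insertion (with its bases) per I run, one
single-base substitution per mismatched M column. Adjacent mismatches stay
single-base — per-position profiles and base-editor reporting need
single-base resolution — and N columns are never substitutions.

A read's *signature* is its canonical sorted event set: all indels in indel
mode, plus in-window substitutions in base-editor mode. Substitutions are
excluded from indel-mode signatures so sequencing errors do not fragment the
table; the signature key includes inserted bases (`6:I:2:GG`), which is the
lossless, finer-grained choice. The empty signature is rendered `WT`.

The *modified* call is scoped by a quantification window: the whole
reference when no cut site is given, else cut site ±10 (overridable). A
deletion qualifies when its footprint intersects the window; an insertion
when its anchor falls in the closed interval [start, end] (insertions live
between bases); substitutions qualify only in base-editor mode. Per-position
profiles count, at each reference position, covering reads (M or D
columns), deletions covering it, insertions anchored at it, and
substitutions at it; fractions divide by depth, defined as 0 at zero depth.
An insertion anchored past the final reference base (a read ending in an
insertion) has no profile row but keeps its place in the signature.

Conservation identities — total = mapped + unmapped + ambiguous; per
reference modified + unmodified = assigned = Σ signature counts; per-position
deletion/substitution counts ≤ depth — are asserted after every tally.

## Reporting

Because all displayed reads share one reference, the "MSA" of top signatures
is a deterministic projection of pairwise alignments onto reference
coordinates: the union of insertion anchors defines extra columns sized to
the longest insertion at each anchor; deletions and absent insertions render
as `-`. De-gapping row 0 returns the reference and de-gapping any read row
returns that read (asserted). The representative read for a signature is the
assigned read of highest mean quality (ties by id). Figures — top-signature
alignment, four-category read accounting, per-position frequencies, and a
per-reference comparison for multi-allele runs — are written as SVG and PNG,
each with a CSV twin carrying the exact plotted numbers; default top-n is 10.

## Simulator

The generator emulates amplicon deep sequencing with a known outcome
spectrum: per read it samples a signature by its spectrum fraction
(remainder unedited), applies the events right-to-left to the reference,
sequences the template single-end (truncated to the read length) or
paired-end (fragment length normal, default 250±25, clamped to
[read length, template]), draws per-base qualities from a truncated normal
(35±3, clipped to [2, 41] — typical recent Illumina values), and substitutes
each base with probability `substitution_error_rate` (default 0.001,
i.e. ~Q30 chemistry). One RNG stream is consumed in a fixed per-read order
(signature, fragment, qualities, errors), so identical specs give identical
output. Truth labels ride in a sidecar TSV, keeping the FASTQ realistic.

What the simulator does *not* model — indel sequencing errors, PCR
duplicates and chimeras, position-dependent quality decay, coupling between
quality and error — bounds what passing tests show: recovery results
demonstrate correctness of the accounting and alignment machinery under
substitution noise, not robustness to PCR artefacts, which real amplicon
data can contain.

## Numerical and degenerate-input choices

- Phred offset fixed at +33; qualities clamped into [0, 60] on input.
- Internal coordinates 0-based half-open everywhere; SAM POS written
  1-based; BED read as-is.
- References must be pure A/C/G/T (user-curated amplicons); reads may
  contain N.
- Zero-length reads survive trimming, fail the length filter, and are
  dropped with their reason counted; an empty FASTQ yields a zeroed summary
  and a complete report inventory.
- A deletion planted at the truncated end of a read is represented as the
  higher-scoring short insertion — an end effect inherent to scoring, which
  is why simulated truth-recovery fixtures keep indels well inside reads.
- On a bare short repeat (e.g. a 9-base `AAAAGAAAA`), a 1-base deletion read
  aligns as a substitution under the default scoring (mismatch 4 < gap 7);
  canonicalization guarantees collapse only among placements the scoring
  actually realises as indels, which in practice means indels embedded in
  unique flanking context.
- WGS regions are extracted with 100-base flanks (clipped at chromosome
  ends, with a warning) so reads overlapping region edges align without
  end-gap artefacts; the prefilter indexes every k-mer (default k=15) of
  each extracted region and its reverse complement, and a read reaching the
  aligner needs only one shared k-mer. Prefilter skips are counted unmapped.

## Problem sizes

The exactness and recovery checks run at 200 random aligner instances,
1,000–2,000 simulated reads per spectrum run, 500 merge pairs, and a 10 kb
toy genome with two 200-base regions — sizes at which every property is
exact and the whole verification suite completes in well under a minute.
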