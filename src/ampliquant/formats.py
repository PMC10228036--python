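"""Strict readers and writers for the file formats the pipeline touches.

Conventions used throughout the package:

* coordinates are 0-based, half-open internally; SAM POS is written 1-based
  as the format requires;
* FASTQ qualities are Phred+33 (modern Illumina); offset-64 input is not
  supported;
* reference names are the first whitespace-delimited token of the FASTA
  header, matching common aligner behaviour;
* ``N`` is legal in reads but illegal in references, which are expected to be
  user-curated amplicon sequences.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

from Bio import SeqIO

READ_ALPHABET = set("ACGTN")
REFERENCE_ALPHABET = set("ACGT")

#: Qualities are clamped into [0, MAX_QUALITY] on input.
MAX_QUALITY = 60
PHRED_OFFSET = 33

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed input file (FASTQ/FASTA/BED/SAM)."""


@dataclass
class Read:
    """One sequencing read: id, uppercase sequence over {A,C,G,T,N}, Phred scores."""

    id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise FormatError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_quality(self) -> float:
        return sum(self.qualities) / len(self.qualities) if self.qualities else 0.0


@dataclass(frozen=True)
class Reference:
    """One named amplicon/allele/region sequence with an optional cut site.

    ``cut_site`` counts reference bases to the left of the expected cleavage
    point (0-based).
    """

    name: str
    sequence: str
    cut_site: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("reference name must be non-empty")
        if len(self.sequence) < 1:
            raise FormatError(f"reference {self.name!r} has empty sequence")
        bad = set(self.sequence) - REFERENCE_ALPHABET
        if bad:
            raise FormatError(
                f"reference {self.name!r} contains illegal bases {sorted(bad)} "
                "(references must be unambiguous A/C/G/T)"
            )
        if self.cut_site is not None and not 0 <= self.cut_site <= len(self.sequence):
            raise FormatError(
                f"reference {self.name!r}: cut site {self.cut_site} outside "
                f"[0, {len(self.sequence)}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Region:
    """A genomic interval of interest (0-based, half-open), e.g. one BED line."""

    chrom: str
    start: int
    end: int
    name: str
    cut_site: Optional[int] = None  # genomic coordinate

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise FormatError(
                f"region {self.name!r}: invalid interval [{self.start}, {self.end})"
            )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _open_maybe_gzip(path: PathLike, mode: str = "rt") -> IO[str]:
    """Open text, transparently decompressing gzip detected by magic bytes."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode, encoding="utf-8")


def _parse_fastq_records(handle: IO[str], path: PathLike) -> Iterator[Read]:
    index = 0
    while True:
        header = handle.readline()
        if header == "":
            return
        lines = [header, handle.readline(), handle.readline(), handle.readline()]
        if any(line == "" for line in lines):
            raise FormatError(f"{path}: truncated FASTQ record at index {index}")
        lines = [line.rstrip("\n").rstrip("\r") for line in lines]
        if not lines[0].startswith("@"):
            raise FormatError(
                f"{path}: record {index} does not start with '@' "
                f"(got {lines[0][:20]!r})"
            )
        if not lines[2].startswith("+"):
            raise FormatError(f"{path}: record {index} missing '+' separator line")
        read_id = lines[0][1:].split()[0] if len(lines[0]) > 1 else ""
        sequence = lines[1].upper()
        if len(sequence) != len(lines[3]):
            raise FormatError(
                f"{path}: read {read_id!r} sequence/quality length mismatch "
                f"({len(sequence)} vs {len(lines[3])})"
            )
        bad = set(sequence) - READ_ALPHABET
        if bad:
            raise FormatError(f"{path}: read {read_id!r} has illegal bases {sorted(bad)}")
        qualities = []
        for char in lines[3]:
            q = ord(char) - PHRED_OFFSET
            if q < 0:
                raise FormatError(f"{path}: read {read_id!r} has quality below Phred 0")
            qualities.append(min(q, MAX_QUALITY))
        yield Read(id=read_id, sequence=sequence, qualities=qualities)
        index += 1


def read_fastq(
    path: PathLike, paired_with: Optional[PathLike] = None
) -> Iterator[Union[Read, tuple[Read, Read]]]:
    """Stream reads from a (possibly gzipped) 4-line FASTQ file.

    With ``paired_with`` set, yields ``(read1, read2)`` pairs synchronized by
    record index and raises if the two files differ in record count.
    """
    if paired_with is None:
        with _open_maybe_gzip(path) as handle:
            yield from _parse_fastq_records(handle, path)
        return
    with _open_maybe_gzip(path) as h1, _open_maybe_gzip(paired_with) as h2:
        it1 = _parse_fastq_records(h1, path)
        it2 = _parse_fastq_records(h2, paired_with)
        index = 0
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                return
            if r1 is None or r2 is None:
                longer = paired_with if r1 is None else path
                raise FormatError(
                    f"paired FASTQ files have unequal record counts "
                    f"(extra record {index} in {longer})"
                )
            yield r1, r2
            index += 1


def write_fastq(reads: Iterable[Read], path: PathLike, compress: bool = False) -> None:
    opener = gzip.open if compress else open
    with opener(path, "wt") as handle:  # type: ignore[operator]
        for read in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in read.qualities)
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


def read_fasta(path: PathLike) -> list[Reference]:
    """Read an ordered reference set from FASTA (multi-line, case folded).

    Cut sites are not encoded in FASTA; they are supplied separately.
    """
    references: list[Reference] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            name = record.id
            if name in seen:
                raise FormatError(f"{path}: duplicate reference name {name!r}")
            seen.add(name)
            sequence = str(record.seq).upper()
            if not sequence:
                raise FormatError(f"{path}: reference {name!r} has empty sequence")
            references.append(Reference(name=name, sequence=sequence))
    if not references:
        raise FormatError(f"{path}: no FASTA records found")
    return references


def write_fasta(entries: Iterable[tuple[str, str]], path: PathLike, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, sequence in entries:
            handle.write(f">{name}\n")
            for i in range(0, len(sequence), width):
                handle.write(sequence[i : i + width] + "\n")


_BED_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path: PathLike) -> list[Region]:
    """Read regions of interest from 3-5 column BED.

    Column 4 is the region name (default ``chrom:start-end``); column 5, when
    present, is an integer cut site in genomic coordinates.
    """
    regions: list[Region] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) >= 4 and fields[3] else f"{chrom}:{start}-{end}"
            cut_site = None
            if len(fields) >= 5 and fields[4] not in ("", "."):
                try:
                    cut_site = int(fields[4])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: non-integer cut site {fields[4]!r}"
                    ) from exc
            if name in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate region name {name!r}")
            seen.add(name)
            regions.append(Region(chrom=chrom, start=start, end=end, name=name, cut_site=cut_site))
    return regions


def ops_to_cigar(operations: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{length}{op}" for op, length in operations) or "*"


def write_sam(
    records: Iterable[tuple[Read, Optional[str], Optional["object"]]],
    references: Sequence[Reference],
    path: PathLike,
) -> None:
    """Write single-end SAM: mapped records FLAG 0, unmapped FLAG 4.

    ``records`` yields ``(read, reference_name, alignment)``; pass
    ``(read, None, None)`` for an unmapped read. ``alignment`` must expose
    ``ref_start`` (0-based) and ``operations`` (list of ``(op, length)``).
    """
    names = {ref.name for ref in references}
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("@HD\tVN:1.6\tSO:unsorted\n")
        for ref in references:
            handle.write(f"@SQ\tSN:{ref.name}\tLN:{len(ref.sequence)}\n")
        for read, ref_name, alignment in records:
            qual = "".join(chr(q + PHRED_OFFSET) for q in read.qualities) or "*"
            if ref_name is None or alignment is None:
                handle.write(
                    f"{read.id}\t4\t*\t0\t0\t*\t*\t0\t0\t{read.sequence or '*'}\t{qual}\n"
                )
                continue
            if ref_name not in names:
                raise FormatError(
                    f"alignment names reference {ref_name!r} absent from the header"
                )
            cigar = ops_to_cigar(alignment.operations)
            handle.write(
                f"{read.id}\t0\t{ref_name}\t{alignment.ref_start + 1}\t60\t"
                f"{cigar}\t*\t0\t0\t{read.sequence}\t{qual}\n"
            )
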