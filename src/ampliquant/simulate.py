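"""Seeded simulator of amplicon sequencing reads with a known editing
spectrum.

The generator emulates an amplicon deep-sequencing experiment: each read is
drawn from an editing-outcome spectrum (a list of signatures with
fractions, the remainder being unedited), the corresponding edited template
is sequenced single- or paired-end, per-base qualities come from a truncated
normal, and substitution errors are sprinkled independently per base. Truth
labels (read id -> source signature) are returned alongside, and can be
written to a sidecar TSV so FASTQ stays realistic while tests stay exact.

One RNG stream is consumed in a fixed order per read (signature, fragment,
qualities, errors), so identical specs — including the seed — give identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Union

import numpy as np

from .formats import Read, Reference, reverse_complement, write_fastq
from .quantify import EditEvent, Signature, signature_key


@dataclass(frozen=True)
class QualityModel:
    """Truncated-normal per-base Phred model (mean 35, sd 3, clipped to
    [2, 41] — typical of recent Illumina chemistry)."""

    mean: float = 35.0
    sd: float = 3.0
    minimum: int = 2
    maximum: int = 41


@dataclass(frozen=True)
class SimSpec:
    """Full description of one simulated sample."""

    reference: Reference
    spectrum: tuple[tuple[Signature, float], ...]
    n_reads: int
    read_length: int
    layout: str = "single"  # single | paired
    substitution_error_rate: float = 0.001
    quality_model: QualityModel = QualityModel()
    fragment_mean: float = 250.0
    fragment_sd: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layout not in ("single", "paired"):
            raise ValueError(f"bad layout {self.layout!r}")
        total = sum(fraction for _, fraction in self.spectrum)
        if any(fraction < 0 for _, fraction in self.spectrum) or total > 1 + 1e-9:
            raise ValueError("spectrum fractions must be >= 0 and sum to <= 1")
        if self.n_reads < 0 or self.read_length < 1:
            raise ValueError("n_reads must be >= 0 and read_length >= 1")


def apply_signature(ref_seq: str, signature: Signature) -> str:
    """Apply a signature's events to a reference sequence.

    Events are applied right-to-left so earlier coordinates stay valid.
    """
    edited = ref_seq
    for event in sorted(signature, reverse=True):
        if event.kind == "deletion":
            if event.position + event.length > len(ref_seq):
                raise ValueError(f"deletion {event.key} outside reference")
            edited = edited[: event.position] + edited[event.position + event.length :]
        elif event.kind == "insertion":
            if not 0 <= event.position <= len(ref_seq):
                raise ValueError(f"insertion {event.key} outside reference")
            edited = edited[: event.position] + event.sequence + edited[event.position :]
        else:
            if event.position + event.length > len(ref_seq):
                raise ValueError(f"substitution {event.key} outside reference")
            edited = (
                edited[: event.position]
                + event.sequence
                + edited[event.position + event.length :]
            )
    return edited


def _sample_qualities(rng: np.random.Generator, n: int, model: QualityModel) -> list[int]:
    raw = rng.normal(model.mean, model.sd, size=n)
    return list(np.clip(np.rint(raw), model.minimum, model.maximum).astype(int))


def _add_errors(rng: np.random.Generator, sequence: str, rate: float) -> str:
    if rate <= 0:
        return sequence
    chars = np.array(list(sequence))
    hits = rng.random(len(chars)) < rate
    if not hits.any():
        return sequence
    for idx in np.flatnonzero(hits):
        current = chars[idx]
        choices = [b for b in "ACGT" if b != current]
        chars[idx] = choices[rng.integers(0, 3)]
    return "".join(chars)


SimOutput = tuple[
    Union[list[Read], list[tuple[Read, Read]]],
    dict[str, int],  # read id -> spectrum index (-1 = unedited)
]


def simulate_reads(spec: SimSpec) -> SimOutput:
    """Generate reads and the truth table mapping read ids to the spectrum
    index they were drawn from (-1 for unedited)."""
    rng = np.random.default_rng(spec.seed)
    templates = [apply_signature(spec.reference.sequence, sig) for sig, _ in spec.spectrum]
    fractions = np.array([fraction for _, fraction in spec.spectrum], dtype=float)
    cumulative = np.cumsum(fractions)

    reads: list = []
    truth: dict[str, int] = {}
    for index in range(spec.n_reads):
        read_id = f"sim_{index:06d}"
        u = rng.random()
        sig_index = int(np.searchsorted(cumulative, u, side="right"))
        if sig_index >= len(templates):
            sig_index = -1
            template = spec.reference.sequence
        else:
            template = templates[sig_index]
        truth[read_id] = sig_index
        if spec.layout == "single":
            fragment = template[: spec.read_length] if len(template) > spec.read_length else template
            qualities = _sample_qualities(rng, len(fragment), spec.quality_model)
            sequence = _add_errors(rng, fragment, spec.substitution_error_rate)
            reads.append(Read(id=read_id, sequence=sequence, qualities=qualities))
        else:
            if spec.read_length > len(template):
                raise ValueError(
                    f"read_length {spec.read_length} exceeds template length "
                    f"{len(template)} for paired layout"
                )
            for attempt in range(100):
                frag_len = int(round(rng.normal(spec.fragment_mean, spec.fragment_sd)))
                if spec.read_length <= frag_len <= len(template):
                    break
            else:
                raise ValueError(
                    "could not sample a fragment between read_length and template "
                    "length in 100 attempts"
                )
            start = int(rng.integers(0, len(template) - frag_len + 1))
            fragment = template[start : start + frag_len]
            r1_seq = fragment[: spec.read_length]
            r2_seq = reverse_complement(fragment[-spec.read_length :])
            q1 = _sample_qualities(rng, len(r1_seq), spec.quality_model)
            q2 = _sample_qualities(rng, len(r2_seq), spec.quality_model)
            r1_seq = _add_errors(rng, r1_seq, spec.substitution_error_rate)
            r2_seq = _add_errors(rng, r2_seq, spec.substitution_error_rate)
            reads.append(
                (
                    Read(id=read_id, sequence=r1_seq, qualities=q1),
                    Read(id=read_id, sequence=r2_seq, qualities=q2),
                )
            )
    return reads, truth


def write_truth_tsv(truth: dict[str, int], spec: SimSpec, path) -> None:
    """Sidecar truth table: read id, spectrum index, signature key."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("read_id\tspectrum_index\tsignature\n")
        for read_id, index in truth.items():
            key = signature_key(spec.spectrum[index][0]) if index >= 0 else signature_key(())
            handle.write(f"{read_id}\t{index}\t{key}\n")


def write_simulated_fastq(reads, path1, path2=None, compress: bool = False) -> None:
    """Write single-end reads to one FASTQ, or pairs to two."""
    if path2 is None:
        write_fastq(reads, path1, compress=compress)
    else:
        write_fastq((pair[0] for pair in reads), path1, compress=compress)
        write_fastq((pair[1] for pair in reads), path2, compress=compress)


def _event_from_dict(data: dict) -> EditEvent:
    return EditEvent(
        position=int(data["position"]),
        kind=data["kind"],
        length=int(data["length"]),
        sequence=data.get("sequence", ""),
    )


def spec_from_json(path) -> SimSpec:
    """Load a SimSpec from a JSON config (the `simulate` CLI input)."""
    with open(path, encoding="utf-8") as handle:
        data = json.load(handle)
    reference = Reference(
        name=data["reference"]["name"],
        sequence=data["reference"]["sequence"].upper(),
        cut_site=data["reference"].get("cut_site"),
    )
    spectrum = tuple(
        (tuple(sorted(_event_from_dict(e) for e in entry["events"])), float(entry["fraction"]))
        for entry in data.get("spectrum", [])
    )
    quality = data.get("quality_model", {})
    return SimSpec(
        reference=reference,
        spectrum=spectrum,
        n_reads=int(data["n_reads"]),
        read_length=int(data["read_length"]),
        layout=data.get("layout", "single"),
        substitution_error_rate=float(data.get("substitution_error_rate", 0.001)),
        quality_model=QualityModel(
            mean=float(quality.get("mean", 35.0)),
            sd=float(quality.get("sd", 3.0)),
            minimum=int(quality.get("minimum", 2)),
            maximum=int(quality.get("maximum", 41)),
        ),
        fragment_mean=float(data.get("fragment_mean", 250.0)),
        fragment_sd=float(data.get("fragment_sd", 25.0)),
        seed=int(data.get("seed", 0)),
    )
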