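import pytest

from ampliquant.align import assign_to_reference
from ampliquant.formats import reverse_complement
from ampliquant.quantify import EditEvent, Window, extract_edits, signature_of
from ampliquant.simulate import (
    QualityModel,
    SimSpec,
    apply_signature,
    simulate_reads,
    spec_from_json,
    write_simulated_fastq,
    write_truth_tsv,
)

REF20 = "ACGGTCATTGCAAGGCTTAA"


class TestApplySignature:
    def test_empty_signature_identity(self):
        assert apply_signature(REF20, ()) == REF20

    def test_deletion(self):
        sig = (EditEvent(position=8, kind="deletion", length=3),)
        assert apply_signature(REF20, sig) == "ACGGTCATAAGGCTTAA"

    def test_insertion(self):
        sig = (EditEvent(position=6, kind="insertion", length=2, sequence="GG"),)
        assert apply_signature(REF20, sig) == "ACGGTCGGATTGCAAGGCTTAA"

    def test_substitution(self):
        sig = (EditEvent(position=0, kind="substitution", length=1, sequence="T"),)
        assert apply_signature(REF20, sig) == "T" + REF20[1:]

    def test_multi_event_right_to_left(self):
        sig = (
            EditEvent(position=2, kind="deletion", length=1),
            EditEvent(position=10, kind="insertion", length=1, sequence="T"),
        )
        assert apply_signature(REF20, sig) == REF20[:2] + REF20[3:10] + "T" + REF20[10:]

    def test_out_of_range_event_rejected(self):
        sig = (EditEvent(position=19, kind="deletion", length=5),)
        with pytest.raises(ValueError):
            apply_signature(REF20, sig)


def base_spec(reference, **overrides):
    defaults = dict(
        reference=reference,
        spectrum=((
            (EditEvent(position=8, kind="deletion", length=3),),
            0.30,
        ),),
        n_reads=100,
        read_length=len(reference.sequence),
        substitution_error_rate=0.0,
        seed=12,
    )
    defaults.update(overrides)
    return SimSpec(**defaults)


class TestSimulateReads:
    def test_zero_reads(self, reference):
        reads, truth = simulate_reads(base_spec(reference, n_reads=0))
        assert reads == [] and truth == {}

    def test_error_free_reads_equal_templates(self, reference, del3_signature):
        spec = base_spec(reference, spectrum=((del3_signature, 1.0),))
        reads, truth = simulate_reads(spec)
        template = apply_signature(reference.sequence, del3_signature)
        assert all(read.sequence == template for read in reads)
        assert all(v == 0 for v in truth.values())

    def test_same_seed_identical_output(self, reference, tmp_path):
        spec = base_spec(reference, substitution_error_rate=0.01)
        out1, out2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        for out in (out1, out2):
            reads, _ = simulate_reads(spec)
            write_simulated_fastq(reads, out)
        assert out1.read_bytes() == out2.read_bytes()

    def test_different_seeds_differ(self, reference):
        spec_a = base_spec(reference, substitution_error_rate=0.05, seed=1)
        spec_b = base_spec(reference, substitution_error_rate=0.05, seed=2)
        reads_a, _ = simulate_reads(spec_a)
        reads_b, _ = simulate_reads(spec_b)
        assert [r.sequence for r in reads_a] != [r.sequence for r in reads_b]

    def test_quality_model_bounds(self, reference):
        model = QualityModel(mean=35, sd=3, minimum=2, maximum=41)
        reads, _ = simulate_reads(base_spec(reference, quality_model=model))
        quals = [q for read in reads for q in read.qualities]
        assert min(quals) >= 2 and max(quals) <= 41

    def test_paired_layout_covers_fragment_ends(self, reference, del3_signature):
        spec = base_spec(
            reference,
            layout="paired",
            read_length=100,
            fragment_mean=160.0,
            fragment_sd=10.0,
        )
        pairs, truth = simulate_reads(spec)
        assert len(pairs) == 100
        for r1, r2 in pairs:
            assert len(r1) == 100 and len(r2) == 100
            template = (
                apply_signature(reference.sequence, del3_signature)
                if truth[r1.id] == 0
                else reference.sequence
            )
            assert r1.sequence in template
            assert reverse_complement(r2.sequence) in template

    def test_paired_read_longer_than_template_rejected(self, reference):
        spec = base_spec(reference, layout="paired", read_length=500)
        with pytest.raises(ValueError):
            simulate_reads(spec)

    def test_round_trip_through_align_and_quantify(self, reference, del3_signature):
        insertion_sig = (EditEvent(position=40, kind="insertion", length=2, sequence="GG"),)
        spec = base_spec(
            reference,
            spectrum=((del3_signature, 0.3), (insertion_sig, 0.2)),
            n_reads=200,
        )
        reads, truth = simulate_reads(spec)
        window = Window(0, len(reference.sequence))
        by_index = {0: del3_signature, 1: insertion_sig, -1: ()}
        for read in reads:
            assignment = assign_to_reference(read, [reference])
            assert assignment.status == "mapped"
            events = extract_edits(
                assignment.alignment, read.sequence, reference.sequence
            )
            assert signature_of(events, window) == by_index[truth[read.id]]

    def test_spectrum_realized_fraction_binomial(self, reference, del3_signature):
        spec = base_spec(reference, spectrum=((del3_signature, 0.30),), n_reads=2000)
        _, truth = simulate_reads(spec)
        realized = sum(1 for v in truth.values() if v == 0) / 2000
        se = (0.3 * 0.7 / 2000) ** 0.5
        assert abs(realized - 0.30) <= 3 * se


class TestSidecarAndConfig:
    def test_truth_tsv(self, reference, del3_signature, tmp_path):
        spec = base_spec(reference, n_reads=5)
        _, truth = simulate_reads(spec)
        path = tmp_path / "truth.tsv"
        write_truth_tsv(truth, spec, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "read_id\tspectrum_index\tsignature"
        assert len(lines) == 6
        for line in lines[1:]:
            read_id, index, key = line.split("\t")
            assert key == ("8:D:3" if index == "0" else "WT")

    def test_spec_from_json(self, tmp_path):
        config = {
            "reference": {"name": "amp", "sequence": REF20, "cut_site": 9},
            "spectrum": [
                {
                    "events": [{"position": 8, "kind": "deletion", "length": 3}],
                    "fraction": 0.3,
                }
            ],
            "n_reads": 10,
            "read_length": 20,
            "seed": 3,
        }
        import json

        path = tmp_path / "spec.json"
        path.write_text(json.dumps(config))
        spec = spec_from_json(path)
        assert spec.reference.cut_site == 9
        assert spec.spectrum[0][1] == 0.3
        reads, _ = simulate_reads(spec)
        assert len(reads) == 10


def test_spectrum_fractions_validated(reference, del3_signature):
    with pytest.raises(ValueError):
        SimSpec(
            reference=reference,
            spectrum=((del3_signature, 0.7), ((), 0.5)),
            n_reads=1,
            read_length=10,
        )
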