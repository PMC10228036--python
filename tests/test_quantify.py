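import pytest

from ampliquant.align import semiglobal_align
from ampliquant.formats import Reference
from ampliquant.quantify import (
    EditEvent,
    Window,
    classify_read,
    default_window,
    extract_edits,
    position_frequencies,
    signature_key,
    signature_of,
    tally,
    top_signatures,
)
from ampliquant.simulate import SimSpec, simulate_reads

REF20 = "ACGGTCATTGCAAGGCTTAA"


def align_and_extract(read_seq, ref_seq):
    aln = semiglobal_align(read_seq, ref_seq)
    from ampliquant.align import left_align_indels

    aln = left_align_indels(aln, read_seq, ref_seq)
    return extract_edits(aln, read_seq, ref_seq)


class TestExtractEdits:
    def test_identity_has_no_events(self):
        assert align_and_extract(REF20, REF20) == []

    def test_deletion_event(self):
        events = align_and_extract(REF20[:8] + REF20[11:], REF20)
        assert events == [EditEvent(position=8, kind="deletion", length=3)]

    def test_insertion_event_carries_bases(self):
        events = align_and_extract(REF20[:6] + "GG" + REF20[6:], REF20)
        assert events == [EditEvent(position=6, kind="insertion", length=2, sequence="GG")]

    def test_adjacent_mismatches_stay_single_base(self):
        read = "TT" + REF20[2:]
        events = align_and_extract(read, REF20)
        assert [e.kind for e in events] == ["substitution", "substitution"]
        assert [e.length for e in events] == [1, 1]
        assert [e.position for e in events] == [0, 1]

    def test_n_is_not_a_substitution(self):
        read = REF20[:5] + "N" + REF20[6:]
        assert align_and_extract(read, REF20) == []


class TestClassify:
    window = Window(0, 20)

    def test_no_events_unmodified(self):
        assert not classify_read([], self.window)

    def test_deletion_in_window_modified(self):
        events = [EditEvent(position=8, kind="deletion", length=3)]
        assert classify_read(events, self.window)

    def test_deletion_outside_window_unmodified(self):
        events = [EditEvent(position=50, kind="deletion", length=3)]
        assert not classify_read(events, Window(0, 20))
        assert classify_read(events, Window(48, 60))

    def test_substitution_mode_dependence(self):
        events = [EditEvent(position=10, kind="substitution", length=1, sequence="A")]
        assert not classify_read(events, self.window, mode="indel")
        assert classify_read(events, self.window, mode="base_editor")

    def test_insertion_anchor_window_edges_inclusive(self):
        window = Window(5, 10)
        for anchor, expected in [(4, False), (5, True), (10, True), (11, False)]:
            events = [EditEvent(position=anchor, kind="insertion", length=1, sequence="A")]
            assert classify_read(events, window) is expected


class TestSignature:
    def test_empty(self):
        assert signature_of([], Window(0, 20)) == ()
        assert signature_key(()) == "WT"

    def test_indel_mode_drops_substitutions(self):
        events = [
            EditEvent(position=3, kind="substitution", length=1, sequence="T"),
            EditEvent(position=8, kind="deletion", length=3),
        ]
        sig = signature_of(events, Window(0, 20), mode="indel")
        assert sig == (EditEvent(position=8, kind="deletion", length=3),)
        assert signature_key(sig) == "8:D:3"

    def test_base_editor_mode_keeps_window_substitutions(self):
        events = [
            EditEvent(position=3, kind="substitution", length=1, sequence="T"),
            EditEvent(position=15, kind="substitution", length=1, sequence="C"),
        ]
        sig = signature_of(events, Window(0, 10), mode="base_editor")
        assert sig == (EditEvent(position=3, kind="substitution", length=1, sequence="T"),)

    def test_indels_outside_window_kept_in_signature(self):
        events = [EditEvent(position=50, kind="deletion", length=2)]
        assert signature_of(events, Window(0, 20)) == tuple(events)

    def test_key_format(self):
        assert signature_key((EditEvent(position=6, kind="insertion", length=2, sequence="GG"),)) == "6:I:2:GG"


class TestDefaultWindow:
    def test_whole_reference_without_cut_site(self):
        ref = Reference(name="a", sequence="A" * 50)
        assert default_window(ref) == Window(0, 50)

    def test_cut_site_window_clipped(self):
        ref = Reference(name="a", sequence="A" * 50, cut_site=5)
        assert default_window(ref) == Window(0, 15)
        ref2 = Reference(name="a", sequence="A" * 50, cut_site=48)
        assert default_window(ref2) == Window(38, 50)


def simulate_and_tally(reference, spectrum, n_reads, error_rate, seed, mode="indel"):
    from ampliquant.align import assign_to_reference

    spec = SimSpec(
        reference=reference,
        spectrum=spectrum,
        n_reads=n_reads,
        read_length=len(reference.sequence),
        substitution_error_rate=error_rate,
        seed=seed,
    )
    reads, truth = simulate_reads(spec)
    assignments = [assign_to_reference(read, [reference]) for read in reads]
    summary = tally(zip(reads, assignments), [reference], mode=mode)
    return summary, truth


class TestTally:
    def test_counts_and_signature_table(self, reference, del3_signature):
        summary, truth = simulate_and_tally(
            reference, ((del3_signature, 0.5),), n_reads=10, error_rate=0.0, seed=1
        )
        realized = sum(1 for v in truth.values() if v == 0)
        ref_summary = summary.per_reference[reference.name]
        assert summary.total_reads == 10
        assert summary.mapped_reads == 10
        assert ref_summary.modified_reads == realized
        assert ref_summary.signature_counts.get(del3_signature, 0) == realized
        assert ref_summary.signature_counts.get((), 0) == 10 - realized

    def test_zero_reads(self, reference):
        summary = tally([], [reference])
        assert summary.total_reads == 0
        assert summary.per_reference[reference.name].assigned_reads == 0

    def test_conservation_identities(self, reference, del3_signature):
        summary, _ = simulate_and_tally(
            reference, ((del3_signature, 0.3),), n_reads=300, error_rate=0.005, seed=9
        )
        summary.check()  # raises on any broken identity
        ref_summary = summary.per_reference[reference.name]
        assert (
            ref_summary.modified_reads + ref_summary.unmodified_reads
            == ref_summary.assigned_reads
        )

    def test_parameter_recovery_error_free(self, reference, del3_signature):
        summary, truth = simulate_and_tally(
            reference, ((del3_signature, 0.3),), n_reads=2000, error_rate=0.0, seed=17
        )
        realized = sum(1 for v in truth.values() if v == 0)
        ref_summary = summary.per_reference[reference.name]
        assert ref_summary.modified_reads == realized
        assert ref_summary.signature_counts[del3_signature] == realized

    def test_parameter_recovery_with_noise(self, reference, del3_signature):
        summary, truth = simulate_and_tally(
            reference, ((del3_signature, 0.3),), n_reads=2000, error_rate=0.001, seed=17
        )
        realized_fraction = sum(1 for v in truth.values() if v == 0) / 2000
        ref_summary = summary.per_reference[reference.name]
        measured = ref_summary.modified_reads / ref_summary.assigned_reads
        assert abs(measured - realized_fraction) <= 0.01

    def test_signature_grouping_on_repetitive_reference(self):
        # every placement of a 1-base deletion inside the homopolymer run of
        # "CCAAAAACC" reproduces the same read; all must collapse to one
        # signature after left-alignment
        ref = Reference(name="rep", sequence="CCAAAAACC")
        from ampliquant.align import Alignment, left_align_indels

        read = "CCAAAACC"
        signatures = set()
        for del_pos in range(2, 7):
            ops = (("M", del_pos), ("D", 1), ("M", len(ref.sequence) - del_pos - 1))
            candidate = Alignment(ref_start=0, score=0, operations=ops)
            shifted = left_align_indels(candidate, read, ref.sequence)
            events = extract_edits(shifted, read, ref.sequence)
            assert not any(e.kind == "substitution" for e in events)
            signatures.add(signature_of(events, Window(0, len(ref.sequence))))
        assert len(signatures) == 1
        (sig,) = signatures
        assert signature_key(sig) == "2:D:1"


class TestTables:
    def build_summary(self, reference, del3_signature):
        summary, truth = simulate_and_tally(
            reference, ((del3_signature, 0.4),), n_reads=50, error_rate=0.0, seed=4
        )
        return summary, truth

    def test_position_frequencies(self, reference, del3_signature):
        summary, truth = self.build_summary(reference, del3_signature)
        realized = sum(1 for v in truth.values() if v == 0)
        table = position_frequencies(summary, reference.name)
        assert len(table) == len(reference.sequence)
        for pos in (8, 9, 10):
            row = table.iloc[pos]
            assert row["deletion_count"] == realized
            assert row["deletion_fraction"] == pytest.approx(realized / 50)
        assert table["deletion_count"].sum() == realized * 3
        assert ((table["deletion_fraction"] >= 0) & (table["deletion_fraction"] <= 1)).all()
        assert (table["substitution_count"] == 0).all()

    def test_depth_zero_positions_have_zero_fractions(self, reference):
        summary = tally([], [reference])
        table = position_frequencies(summary, reference.name)
        assert (table["depth"] == 0).all()
        assert (table["deletion_fraction"] == 0).all()

    def test_unknown_reference_rejected(self, reference):
        summary = tally([], [reference])
        with pytest.raises(KeyError):
            position_frequencies(summary, "ghost")
        with pytest.raises(KeyError):
            top_signatures(summary, "ghost")

    def test_top_signatures_order_and_percentages(self, reference, del3_signature):
        summary, truth = self.build_summary(reference, del3_signature)
        realized = sum(1 for v in truth.values() if v == 0)
        table = top_signatures(summary, reference.name, n=2)
        assert len(table) == 2
        counts = dict(zip(table["signature"], table["read_count"]))
        assert counts["8:D:3"] == realized
        assert counts["WT"] == 50 - realized
        assert table["read_count"].is_monotonic_decreasing
        assert table["percentage"].sum() == pytest.approx(100.0)

    def test_top_signatures_n_larger_than_distinct(self, reference, del3_signature):
        summary, _ = self.build_summary(reference, del3_signature)
        table = top_signatures(summary, reference.name, n=50)
        assert len(table) == 2
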