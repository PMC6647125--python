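"""Event model: grammar validation, pull/push consumption, laziness."""

import io

import pytest

from phylostream import (EdgeInfo, Event, EventType, PullReader, Topology,
                         push_dispatch, validate_stream)
from phylostream.events import end, sole, start
from phylostream.formats.fasta import FastaReader


def _doc(*inner):
    return [start(EventType.DOCUMENT, "d"), *inner, end(EventType.DOCUMENT)]


def fig4_style_stream():
    """An OTU list plus an alignment referencing it, sequences referencing
    the OTUs — the canonical cross-referenced document shape."""
    return _doc(
        start(EventType.OTU_LIST, "ol1"),
        start(EventType.OTU, "o1", label="a"), end(EventType.OTU),
        start(EventType.OTU, "o2", label="b"), end(EventType.OTU),
        end(EventType.OTU_LIST),
        start(EventType.ALIGNMENT, "al1", linked_id="ol1"),
        start(EventType.SEQUENCE, "s1", linked_id="o1"),
        sole(EventType.SEQUENCE_TOKENS, payload=["A", "C"]),
        end(EventType.SEQUENCE),
        start(EventType.SEQUENCE, "s2", linked_id="o2"),
        sole(EventType.SEQUENCE_TOKENS, payload=["A", "G"]),
        end(EventType.SEQUENCE),
        end(EventType.ALIGNMENT),
    )


class TestValidateStream:
    def test_empty_document_is_valid(self):
        assert validate_stream(_doc()).valid

    def test_cross_referenced_document_is_valid(self):
        report = validate_stream(fig4_style_stream())
        assert report.valid and not report.violations

    def test_forward_reference_rejected(self):
        events = _doc(
            start(EventType.ALIGNMENT, "al1"),
            start(EventType.SEQUENCE, "s1", linked_id="o1"),  # o1 comes later
            end(EventType.SEQUENCE),
            end(EventType.ALIGNMENT),
            start(EventType.OTU_LIST, "ol1"),
            start(EventType.OTU, "o1"), end(EventType.OTU),
            end(EventType.OTU_LIST),
        )
        report = validate_stream(events)
        assert not report.valid
        assert "FORWARD_REFERENCE" in [v.code for v in report.violations]

    def test_duplicate_id_rejected(self):
        events = _doc(
            start(EventType.OTU_LIST, "x"),
            start(EventType.OTU, "x"), end(EventType.OTU),
            end(EventType.OTU_LIST),
        )
        report = validate_stream(events)
        assert [v.code for v in report.violations] == ["DUPLICATE_ID"]

    def test_unbalanced_stream_rejected(self):
        events = [start(EventType.DOCUMENT, "d"),
                  start(EventType.OTU_LIST, "ol")]
        report = validate_stream(events)
        assert not report.valid
        assert "UNBALANCED" in [v.code for v in report.violations]

    def test_sole_only_types_reject_start_end(self):
        events = _doc(
            start(EventType.ALIGNMENT, "al"),
            start(EventType.SEQUENCE, "s"),
            Event(EventType.SEQUENCE_TOKENS, Topology.START, id="t"),
            end(EventType.SEQUENCE),
            end(EventType.ALIGNMENT),
        )
        report = validate_stream(events)
        assert "TOPOLOGY" in [v.code for v in report.violations]

    def test_out_of_order_children_rejected(self):
        # sets must follow the member elements inside an OTU list
        events = _doc(
            start(EventType.OTU_LIST, "ol"),
            start(EventType.OTU_SET, "s1", payload=[]),
            end(EventType.OTU_SET),
            start(EventType.OTU, "o1"), end(EventType.OTU),
            end(EventType.OTU_LIST),
        )
        report = validate_stream(events)
        assert "GRAMMAR_ORDER" in [v.code for v in report.violations]

    def test_multiple_parents_in_tree_rejected(self):
        events = _doc(
            start(EventType.TREE_NETWORK_GROUP, "g"),
            start(EventType.TREE, "t"),
            start(EventType.NODE, "n1"), end(EventType.NODE),
            start(EventType.NODE, "n2"), end(EventType.NODE),
            start(EventType.NODE, "n3"), end(EventType.NODE),
            start(EventType.EDGE, "e1", payload=EdgeInfo("n1", "n3")),
            end(EventType.EDGE),
            start(EventType.EDGE, "e2", payload=EdgeInfo("n2", "n3")),
            end(EventType.EDGE),
            end(EventType.TREE),
            end(EventType.TREE_NETWORK_GROUP),
        )
        report = validate_stream(events)
        assert "MULTIPLE_PARENTS" in [v.code for v in report.violations]

    def test_shared_edge_targets_allowed_in_network(self):
        events = _doc(
            start(EventType.TREE_NETWORK_GROUP, "g"),
            start(EventType.NETWORK, "t"),
            start(EventType.NODE, "n1"), end(EventType.NODE),
            start(EventType.NODE, "n2"), end(EventType.NODE),
            start(EventType.NODE, "n3"), end(EventType.NODE),
            start(EventType.EDGE, "e1", payload=EdgeInfo("n1", "n3")),
            end(EventType.EDGE),
            start(EventType.EDGE, "e2", payload=EdgeInfo("n2", "n3")),
            end(EventType.EDGE),
            end(EventType.NETWORK),
            end(EventType.TREE_NETWORK_GROUP),
        )
        assert validate_stream(events).valid

    def test_malformed_stream_never_raises(self, corpus):
        # shuffling a valid stream must yield violations, not exceptions
        import random
        rng = random.Random(1)
        for _spec, events in corpus[:5]:
            shuffled = list(events)
            rng.shuffle(shuffled)
            validate_stream(shuffled)  # must not raise

    def test_corpus_streams_all_valid(self, corpus):
        for spec, events in corpus:
            report = validate_stream(events)
            assert report.valid, (spec, report.violations[:3])


class TestConsumptionModes:
    FASTA = ">a\nACGT\n>b\nACGA\n"

    def test_pull_and_push_sequences_identical(self):
        pulled = list(FastaReader(self.FASTA).events())
        received: list = []
        push_dispatch(FastaReader(self.FASTA).events(), [received.append])
        assert received == pulled

    def test_two_listeners_receive_identical_sequences(self):
        first: list = []
        second: list = []
        push_dispatch(FastaReader(self.FASTA).events(),
                      [first.append, second.append])
        assert first == second and len(first) > 0

    def test_push_without_listeners_is_an_error(self):
        with pytest.raises(ValueError):
            push_dispatch(FastaReader(self.FASTA).events(), [])

    def test_listener_exception_propagates(self):
        def boom(_ev):
            raise RuntimeError("listener failure")

        with pytest.raises(RuntimeError):
            push_dispatch(FastaReader(self.FASTA).events(), [boom])


class CountingLines:
    """Line source instrumenting how much input a reader has consumed."""

    def __init__(self, text):
        self.lines = text.splitlines(keepends=True)
        self.consumed = 0

    def __iter__(self):
        for line in self.lines:
            self.consumed += 1
            yield line

    def read(self):
        return "".join(self.lines)


class TestLaziness:
    def test_partial_consumption_reads_bounded_input(self):
        text = ">s1\n" + "ACGT\n" * 500
        source = CountingLines(text)
        reader = PullReader(FastaReader(source).events())
        for _ in range(3):
            next(reader)
        reader.close()
        # DOC, ALIGNMENT, SEQUENCE starts need the header and at most a
        # line of read-ahead
        assert source.consumed <= 3

    def test_streaming_keeps_constant_event_retention(self):
        # a large alignment flows through without event accumulation
        lines = [">s1"] + ["ACGTACGTAC" * 10] * 100
        reader = PullReader(FastaReader("\n".join(lines)).events())
        tokens = 0
        for ev in reader:
            if ev.type is EventType.SEQUENCE_TOKENS:
                tokens += len(ev.payload)
        assert tokens == 100 * 100
        assert reader.max_buffered <= 1
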