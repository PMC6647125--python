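"""FASTA and PHYLIP readers/writers, MEGA reader."""

import pytest

from phylostream import (EventType, FormatError, Topology, WriteError,
                         events_to_adapter, validate_stream)
from phylostream.formats.fasta import FastaReader, FastaWriter
from phylostream.formats.mega import MegaReader
from phylostream.formats.phylip import (PhylipDialect, PhylipReader,
                                        PhylipWriter)


def tokens_of(events):
    out = {}
    label = None
    for ev in events:
        if ev.type is EventType.SEQUENCE and ev.topology is Topology.START:
            label = ev.label
            out[label] = []
        elif ev.type is EventType.SEQUENCE_TOKENS:
            out[label].extend(ev.payload)
    return out


class TestFastaReading:
    def test_record_with_description_metadata(self):
        events = list(FastaReader(">s1 human\nACGT").events())
        assert validate_stream(events).valid
        assert tokens_of(events) == {"s1": list("ACGT")}
        metas = [ev for ev in events if ev.type is EventType.LITERAL_META
                 and ev.topology is Topology.START]
        assert metas[0].payload.string_key == "description"
        contents = [ev for ev in events
                    if ev.type is EventType.LITERAL_META_CONTENT]
        assert contents[0].payload.value == "human"

    def test_column_indices_stripped(self):
        events = list(FastaReader(">s\n1 ACGT\n5 GGCC").events())
        assert tokens_of(events) == {"s": list("ACGTGGCC")}

    def test_column_indices_kept_when_disallowed(self):
        events = list(FastaReader(">s\n5 GGCC",
                                  allow_column_indices=False).events())
        assert tokens_of(events) == {"s": list("5GGCC")}

    def test_empty_stream_is_empty_document(self):
        events = list(FastaReader("").events())
        assert [ev.type for ev in events] == [EventType.DOCUMENT,
                                              EventType.DOCUMENT]

    def test_semicolon_lines_become_comments(self):
        events = list(FastaReader(">s\nAC\n;remark\nGT").events())
        comments = [ev for ev in events if ev.type is EventType.COMMENT]
        assert [c.payload for c in comments] == ["remark"]

    def test_data_before_header_rejected(self):
        with pytest.raises(FormatError):
            list(FastaReader("ACGT\n>s\nAC").events())


class TestFastaWriting:
    def test_round_trip_preserves_labels_and_tokens(self):
        source = ">one\nACGTAC\n>two\nGGTTAA\n"
        doc = events_to_adapter(FastaReader(source).events())
        text, result = FastaWriter().write_to_string(doc)
        again = tokens_of(FastaReader(text).events())
        assert again == tokens_of(FastaReader(source).events())
        assert not any(ch.isdigit() for line in text.splitlines()
                       for ch in line if not line.startswith(">"))

    def test_line_wrapping(self):
        doc = events_to_adapter(FastaReader(">s\n" + "A" * 25).events())
        text, _ = FastaWriter().write_to_string(doc, line_length=10)
        body = [l for l in text.splitlines() if not l.startswith(">")]
        assert body == ["A" * 10, "A" * 10, "A" * 5]

    def test_metadata_dropped_with_one_warning(self):
        doc = events_to_adapter(FastaReader(">s1 annotated\nACGT").events())
        text, result = FastaWriter().write_to_string(doc)
        assert result.warnings.count("METADATA_DROPPED") == 1
        assert ">s1\n" in text

    def test_empty_document_writes_nothing(self):
        doc = events_to_adapter(FastaReader("").events())
        text, result = FastaWriter().write_to_string(doc)
        assert text == "" and len(result.warnings) == 0

    def test_multicharacter_token_rejected(self):
        nexus_like = events_to_adapter(FastaReader(">s\nAC").events())
        nexus_like.matrices[0].sequences[
            next(iter(nexus_like.matrices[0].sequences))
        ].content[0].payload[0] = "A1B"
        with pytest.raises(WriteError) as err:
            FastaWriter().write_to_string(nexus_like)
        assert err.value.code == "UNWRITABLE_TOKEN"


STANDARD_PHYLIP = " 2 4\nA         ACGT\nB         ACGA\n"


class TestPhylipReading:
    def test_standard_sequential(self):
        events = list(PhylipReader(STANDARD_PHYLIP).events())
        assert validate_stream(events).valid
        assert tokens_of(events) == {"A": list("ACGT"), "B": list("ACGA")}

    def test_interleaved_equals_sequential(self):
        interleaved = " 2 4\nA         AC\nB         AC\nGT\nGA\n"
        dialect = PhylipDialect(layout="interleaved")
        assert tokens_of(PhylipReader(interleaved, dialect).events()) == \
            tokens_of(PhylipReader(STANDARD_PHYLIP).events())

    def test_relaxed_names_end_at_whitespace(self):
        text = " 1 4\nvery_long_taxon_name ACGT\n"
        dialect = PhylipDialect(variant="relaxed")
        assert tokens_of(PhylipReader(text, dialect).events()) == {
            "very_long_taxon_name": list("ACGT")}

    def test_empty_dimensions_valid(self):
        events = list(PhylipReader(" 0 0\n").events())
        assert validate_stream(events).valid
        assert tokens_of(events) == {}

    def test_dimension_mismatch_names_offender(self):
        with pytest.raises(FormatError) as err:
            list(PhylipReader(" 2 4\nA         ACGTT\nB         ACGA")
                 .events())
        assert err.value.code == "DIMENSION_MISMATCH"
        assert "'A'" in str(err.value)


class TestPhylipWriting:
    def test_short_names_untouched(self):
        doc = events_to_adapter(PhylipReader(STANDARD_PHYLIP).events())
        text, result = PhylipWriter().write_to_string(doc)
        assert result.name_map.touched == set()
        assert tokens_of(PhylipReader(text).events()) == \
            tokens_of(PhylipReader(STANDARD_PHYLIP).events())

    def test_long_names_shortened_uniquely_with_map(self):
        fasta = ">taxon_name_longer_1\nACGT\n>taxon_name_longer_2\nACGA\n"
        doc = events_to_adapter(FastaReader(fasta).events())
        text, result = PhylipWriter().write_to_string(doc)
        written = result.name_map.written()
        assert len(set(written)) == 2 and all(len(w) <= 10 for w in written)
        # re-read and map back to the original labels
        inverse = result.name_map.inverse()
        again = tokens_of(PhylipReader(text).events())
        restored = {inverse[name]: toks for name, toks in again.items()}
        assert restored == tokens_of(FastaReader(fasta).events())
        assert result.warnings.count("LABEL_EDITED") == 2

    def test_unaligned_matrix_rejected(self):
        doc = events_to_adapter(FastaReader(">a\nACGT\n>b\nAC").events())
        with pytest.raises(WriteError) as err:
            PhylipWriter().write_to_string(doc)
        assert err.value.code == "UNALIGNED_MATRIX"


MEGA_DOC = """#mega
!Title Primate data;
!Description test alignment;
#one
ACGT
#two
AC.A
"""


class TestMegaReading:
    def test_title_and_description_metadata(self):
        events = list(MegaReader(MEGA_DOC).events())
        assert validate_stream(events).valid
        keys = [ev.payload.string_key for ev in events
                if ev.type is EventType.LITERAL_META
                and ev.topology is Topology.START]
        assert keys == ["title", "description"]

    def test_identity_marker_expanded_from_first_sequence(self):
        # '.' at column 2 copies the first sequence's token there ('G')
        events = list(MegaReader(MEGA_DOC).events())
        assert tokens_of(events) == {"one": list("ACGT"),
                                     "two": list("ACGA")}

    def test_gene_statements_become_character_sets(self):
        text = "#mega\n#s1\n!Gene=g1;\nAC\n!Gene=g2;\nGT\n#s1\n"
        # interleaved form: gene markers at columns 0 and 2
        text = ("#mega\n!Gene=g1;\n#s1\nAC\n#s2\nAC\n"
                "!Gene=g2;\n#s1\nGT\n#s2\nGT\n")
        events = list(MegaReader(text).events())
        sets = [(ev.label, ev.payload) for ev in events
                if ev.type is EventType.CHARACTER_SET
                and ev.topology is Topology.START]
        assert sets == [("g1", [(0, 2)]), ("g2", [(2, 4)])]

    def test_missing_magic_rejected(self):
        with pytest.raises(FormatError):
            list(MegaReader("#s1\nACGT").events())
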