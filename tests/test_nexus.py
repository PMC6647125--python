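"""NEXUS block/command framework: reading, writing, linking, sets."""

import random

import pytest

from phylostream import (EventType, FormatError, Topology, build_meta_tree,
                         events_to_adapter, validate_stream)
from phylostream.formats.nexus import (NexusReader, NexusWriter,
                                       intervals_to_nexus_ranges,
                                       nexus_ranges_to_intervals,
                                       register_handler, tokenize_nexus)
from test_text_formats import tokens_of


def read(text, **params):
    return list(NexusReader(text, **params).events())


class TestTokenizer:
    def test_block_structure(self):
        tokens = tokenize_nexus("#NEXUS BEGIN TAXA; END;")
        values = [(t.kind, t.value) for t in tokens]
        assert ("word", "BEGIN") in values and ("word", "TAXA") in values

    def test_quoted_word_keeps_spaces(self):
        tokens = tokenize_nexus("#NEXUS 'a b'")
        assert tokens[-1].value == "a b" and tokens[-1].quoted

    def test_comment_interleaved_between_words(self):
        tokens = tokenize_nexus("#NEXUS A[comment]B")
        assert [(t.kind, t.value) for t in tokens[1:]] == [
            ("word", "A"), ("comment", "comment"), ("word", "B")]

    def test_missing_magic_rejected(self):
        with pytest.raises(FormatError):
            tokenize_nexus("BEGIN TAXA; END;")


class TestTaxaBlock:
    def test_labels_become_otus_in_order(self):
        events = read("#NEXUS BEGIN TAXA; DIMENSIONS NTAX=2; "
                      "TAXLABELS a b; END;")
        assert validate_stream(events).valid
        otus = [ev.label for ev in events if ev.type is EventType.OTU
                and ev.topology is Topology.START]
        assert otus == ["a", "b"]

    def test_ntax_mismatch_rejected(self):
        with pytest.raises(FormatError) as err:
            read("#NEXUS BEGIN TAXA; DIMENSIONS NTAX=3; TAXLABELS a b; END;")
        assert err.value.code == "DIMENSION_MISMATCH"

    def test_duplicate_taxon_rejected(self):
        with pytest.raises(FormatError) as err:
            read("#NEXUS BEGIN TAXA; DIMENSIONS NTAX=2; TAXLABELS a a; END;")
        assert err.value.code == "DUPLICATE_TAXON"


CHARACTERS = """#NEXUS
BEGIN TAXA; DIMENSIONS NTAX=2; TAXLABELS a b; END;
BEGIN CHARACTERS;
DIMENSIONS NCHAR=4;
FORMAT DATATYPE=DNA MATCHCHAR=.;
MATRIX
a ACGT
b AC.T
;
END;
"""


class TestCharactersBlock:
    def test_matchchar_expanded_against_first_row(self):
        # '.' at column 2 copies the first row's token there ('G')
        events = read(CHARACTERS)
        assert tokens_of(events) == {"a": list("ACGT"), "b": list("ACGT")}

    def test_sequences_linked_to_taxa(self):
        events = read(CHARACTERS)
        otu_ids = {ev.label: ev.id for ev in events
                   if ev.type is EventType.OTU
                   and ev.topology is Topology.START}
        links = {ev.label: ev.linked_id for ev in events
                 if ev.type is EventType.SEQUENCE
                 and ev.topology is Topology.START}
        assert links == {"a": otu_ids["a"], "b": otu_ids["b"]}

    def test_unresolvable_sequence_name_rejected(self):
        text = CHARACTERS.replace("b AC.T", "zz ACTT")
        with pytest.raises(FormatError) as err:
            read(text)
        assert err.value.code == "UNRESOLVED_TAXON"

    def test_mixed_datatype_partitions(self):
        text = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=1 NCHAR=6;
FORMAT DATATYPE=MIXED(DNA:1-4,STANDARD:5-6);
MATRIX
a ACGT01
;
END;
"""
        events = read(text)
        assert validate_stream(events).valid
        token_sets = [(ev.label, ev.payload["intervals"]) for ev in events
                      if ev.type is EventType.TOKEN_SET_DEFINITION
                      and ev.topology is Topology.START]
        assert token_sets == [("DNA", [(0, 4)]), ("STANDARD", [(4, 6)])]

    def test_data_block_declares_taxa_inline(self):
        text = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=2 NCHAR=2;
FORMAT DATATYPE=DNA;
MATRIX
x AC
y GT
;
END;
"""
        events = read(text)
        assert validate_stream(events).valid
        otus = [ev.label for ev in events if ev.type is EventType.OTU
                and ev.topology is Topology.START]
        assert otus == ["x", "y"]

    @pytest.mark.parametrize("seed", range(50))
    def test_interleaved_equals_sequential(self, seed):
        """Equivalence oracle: the same random matrix split into
        interleaved blocks parses to identical token streams."""
        rng = random.Random(seed)
        ntax = rng.randrange(2, 6)
        nchar = rng.randrange(2, 30)
        rows = {f"t{i}": [rng.choice("ACGT") for _ in range(nchar)]
                for i in range(ntax)}
        head = (f"#NEXUS BEGIN DATA; DIMENSIONS NTAX={ntax} NCHAR={nchar}; "
                f"FORMAT DATATYPE=DNA{{}};\nMATRIX\n{{}};\nEND;")
        sequential = head.format("", "".join(
            f"{name} {''.join(toks)}\n" for name, toks in rows.items()))
        split = rng.randrange(1, nchar + 1)
        block1 = "".join(f"{name} {''.join(toks[:split])}\n"
                         for name, toks in rows.items())
        block2 = "".join(f"{name} {''.join(toks[split:])}\n"
                         for name, toks in rows.items())
        interleaved = head.format(" INTERLEAVE", block1 + "\n" + block2)
        assert tokens_of(read(sequential)) == rows
        assert tokens_of(read(interleaved)) == tokens_of(read(sequential))

    def test_unaligned_block_permits_unequal_lengths(self):
        text = """#NEXUS
BEGIN UNALIGNED;
DIMENSIONS NTAX=2;
FORMAT DATATYPE=DNA;
MATRIX
a ACGT
b AC
;
END;
"""
        events = read(text)
        assert validate_stream(events).valid
        assert tokens_of(events) == {"a": list("ACGT"), "b": list("AC")}


TREES = """#NEXUS
BEGIN TAXA; DIMENSIONS NTAX=3; TAXLABELS a b c; END;
BEGIN TREES;
TRANSLATE 1 a, 2 b;
TREE t = (1,(2,c)95);
END;
"""


class TestTreesBlock:
    def test_translate_then_label_then_index(self):
        events = read(TREES)
        assert validate_stream(events).valid
        otu_ids = {ev.label: ev.id for ev in events
                   if ev.type is EventType.OTU
                   and ev.topology is Topology.START}
        nodes = {ev.label: ev.linked_id for ev in events
                 if ev.type is EventType.NODE
                 and ev.topology is Topology.START}
        assert nodes["a"] == otu_ids["a"]      # via TRANSLATE
        assert nodes["b"] == otu_ids["b"]      # via TRANSLATE
        assert nodes["c"] == otu_ids["c"]      # via label

    def test_internal_numeric_label_not_translated_by_default(self):
        events = read(TREES)
        nodes = {ev.label: ev.linked_id for ev in events
                 if ev.type is EventType.NODE
                 and ev.topology is Topology.START}
        # "95" stays a support-value label, not taxon index 95
        assert nodes["95"] is None

    def test_internal_translation_can_be_enabled(self):
        text = TREES.replace("(2,c)95", "(2,c)3")
        events = read(text, translate_internal_nodes=True)
        otu_ids = {ev.label: ev.id for ev in events
                   if ev.type is EventType.OTU
                   and ev.topology is Topology.START}
        nodes = {ev.label: ev.linked_id for ev in events
                 if ev.type is EventType.NODE
                 and ev.topology is Topology.START}
        assert nodes["c"] == otu_ids["c"]  # internal "3" -> index -> c

    def test_lookup_order_on_conflicting_keys(self):
        """Brute-force oracle: when a key is simultaneously a TRANSLATE
        entry, a taxon label and an index, the TRANSLATE entry wins; when
        it is label and index, the label wins."""
        text = """#NEXUS
BEGIN TAXA; DIMENSIONS NTAX=3; TAXLABELS 2 3 x; END;
BEGIN TREES;
TRANSLATE 2 x;
TREE t = (2,(3,x_extra));
END;
"""
        # taxon labels are literally "2", "3", "x"; TRANSLATE maps "2"->x.
        events = read(text.replace("x_extra", "1"))
        otu_ids = {ev.label: ev.id for ev in events
                   if ev.type is EventType.OTU
                   and ev.topology is Topology.START}
        nodes = [(ev.label, ev.linked_id) for ev in events
                 if ev.type is EventType.NODE
                 and ev.topology is Topology.START]
        resolved = dict(nodes)
        assert resolved["x"] == otu_ids["x"]   # TRANSLATE beat label "2"
        assert resolved["3"] == otu_ids["3"]   # label beat index 3
        # node "1" fell through to the index lookup: first taxon ("2"),
        # whose label replaces the node's
        assert resolved["2"] == otu_ids["2"]

    def test_unresolvable_terminal_warns_but_parses(self):
        reader = NexusReader(TREES.replace("(2,c)95", "(2,zz)95"))
        events = list(reader.events())
        assert validate_stream(events).valid
        assert reader.warnings.count("UNRESOLVED_LABEL") == 1

    def test_rooting_comment_becomes_tree_metadata(self):
        text = """#NEXUS
BEGIN TREES; TREE t = [&U] (a,b); END;
"""
        doc = events_to_adapter(read(text))
        tree = doc.tree_network_groups[0].members[0]
        meta = build_meta_tree(tree.metadata)
        rooted = [n for n in meta if n.string_key == "rooted"]
        assert rooted and rooted[0].value is False


class TestSetsBlock:
    @pytest.mark.parametrize("entry, expected", [
        (["1-4"], [(0, 4)]),
        (["2-."], [(1, 8)]),
        (["1-6\\3"], [(0, 1), (3, 4)]),
        (["1", "3", "4"], [(0, 1), (2, 4)]),
    ])
    def test_range_conversion(self, entry, expected):
        assert nexus_ranges_to_intervals(entry, 8) == expected

    def test_range_out_of_bounds(self):
        with pytest.raises(FormatError) as err:
            nexus_ranges_to_intervals(["7-9"], 8)
        assert err.value.code == "RANGE_OUT_OF_BOUNDS"

    def test_interval_rendering_back_to_one_based(self):
        assert intervals_to_nexus_ranges([(0, 4), (5, 6)]) == "1-4 6"

    def test_charset_taxset_treeset_events(self):
        text = """#NEXUS
BEGIN TAXA; DIMENSIONS NTAX=3; TAXLABELS a b c; END;
BEGIN CHARACTERS;
DIMENSIONS NCHAR=8; FORMAT DATATYPE=DNA;
MATRIX
a ACGTACGT
b ACGTACGA
c ACGTACGC
;
END;
BEGIN TREES; TREE t1 = (a,(b,c)); END;
BEGIN SETS;
CHARSET c1 = 1-4;
TAXSET odd = 1 3;
TREESET all = t1;
END;
"""
        events = read(text)
        assert validate_stream(events).valid
        doc = events_to_adapter(events)
        matrix = doc.matrices[0]
        assert [(s.start.label, s.start.payload)
                for s in matrix.character_sets] == [("c1", [(0, 4)])]
        otu_list = doc.otu_lists[0]
        otu_ids = [o.id for o in otu_list.otus]
        assert otu_list.otu_sets[0].start.payload == [otu_ids[0], otu_ids[2]]
        group = doc.tree_network_groups[0]
        assert group.sets[0].start.payload == [group.members[0].id]


class TestNetworkBlock:
    def test_enewick_network_parsed(self):
        text = """#NEXUS
BEGIN NETWORKS;
NETWORK n = ((a,(b)#H1),(#H1,c));
END;
"""
        doc = events_to_adapter(read(text))
        member = doc.tree_network_groups[0].members[0]
        assert member.is_network
        indeg = {}
        for edge in member.edges:
            t = edge.start.payload.target_id
            indeg[t] = indeg.get(t, 0) + 1
        assert max(indeg.values()) == 2

    def test_empty_block_is_empty_group(self):
        doc = events_to_adapter(read("#NEXUS BEGIN NETWORKS; END;"))
        assert doc.tree_network_groups[0].members == []

    def test_malformed_enewick_errors(self):
        with pytest.raises(FormatError):
            read("#NEXUS BEGIN NETWORKS; NETWORK n = ((a,b; END;")


class TestExtensibility:
    def test_unknown_block_skipped_with_warning(self):
        reader = NexusReader(
            "#NEXUS BEGIN NOTES; TEXT whatever; END; "
            "BEGIN TAXA; DIMENSIONS NTAX=1; TAXLABELS a; END;")
        events = list(reader.events())
        assert validate_stream(events).valid
        assert reader.warnings.count("UNKNOWN_BLOCK_SKIPPED") == 1
        assert [ev.label for ev in events if ev.type is EventType.OTU
                and ev.topology is Topology.START] == ["a"]

    def test_unknown_command_skipped_with_warning(self):
        reader = NexusReader(
            "#NEXUS BEGIN TAXA; DIMENSIONS NTAX=1; "
            "CHARSTATELABELS 1 site1; TAXLABELS a; END;")
        list(reader.events())
        assert reader.warnings.count("UNKNOWN_COMMAND_SKIPPED") == 1

    def test_registered_handler_replaces_default(self):
        calls = []

        def spy(reader, ctx, tokenizer, token_iter):
            calls.append(True)
            reader._command_tokens(token_iter)

        original = NexusReader.handlers.get(("TAXA", "DIMENSIONS"))
        try:
            register_handler("TAXA", "DIMENSIONS", spy)
            read("#NEXUS BEGIN TAXA; DIMENSIONS NTAX=1; TAXLABELS a; END;")
            assert calls == [True]
        finally:
            NexusReader.handlers[("TAXA", "DIMENSIONS")] = original


class TestWriter:
    def test_full_document_round_trip(self, rich_adapter):
        text, result = NexusWriter().write_to_string(rich_adapter)
        events = read(text)
        assert validate_stream(events).valid
        doc2 = events_to_adapter(events)
        assert len(doc2.otu_lists) == len(rich_adapter.otu_lists)
        assert len(doc2.matrices) == len(rich_adapter.matrices)
        for m1, m2 in zip(rich_adapter.matrices, doc2.matrices):
            t1 = [m1.sequence_tokens(s) for s in m1.sequence_ids()]
            t2 = [m2.sequence_tokens(s) for s in m2.sequence_ids()]
            assert t1 == t2

    def test_two_otu_lists_emit_title_and_link(self):
        from phylostream import FixtureSpec, generate_fixture
        doc = events_to_adapter(generate_fixture(FixtureSpec(
            seed=3, n_otu_lists=2, n_matrices=2, n_otus=2, n_sequences=2,
            seq_length=4)))
        text, _ = NexusWriter().write_to_string(doc)
        assert text.count("TITLE ") >= 2
        assert text.count("LINK TAXA") >= 1
        assert validate_stream(read(text)).valid

    def test_duplicate_labels_edited_and_mapped(self):
        from phylostream.formats.fasta import FastaReader
        doc = events_to_adapter(
            FastaReader(">dup\nAC\n>dup\nGT").events())
        text, result = NexusWriter().write_to_string(doc)
        assert result.name_map.touched == {"dup"}
        assert result.warnings.count("LABEL_EDITED") == \
            len([1 for old, new in result.name_map.pairs if old != new])
        assert validate_stream(read(text)).valid

    def test_node_hot_comments_written_for_lowest_level(self):
        doc = events_to_adapter(read("""#NEXUS
BEGIN TREES; TREE t = (a[&support=0.95]:1.0,b:2.0); END;
"""))
        text, _ = NexusWriter().write_to_string(doc)
        assert "[&support=0.95]" in text
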