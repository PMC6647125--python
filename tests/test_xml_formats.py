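"""NeXML (lossless) and phyloXML (mapped-subset) readers and writers."""

import xml.etree.ElementTree as ET

import pytest

from phylostream import (EventType, FormatError, FixtureSpec, Topology,
                         WriteError, build_meta_tree, events_to_adapter,
                         generate_fixture, validate_stream)
from phylostream.formats.nexml import NexmlReader, NexmlWriter
from phylostream.formats.phyloxml import (DROP_NON_REPRESENTABLE,
                                          FLATTEN_LEAVES_TO_PROPERTIES,
                                          PhyloXmlReader, PhyloXmlWriter)

NEXML_DOC = """<nexml xmlns="http://www.nexml.org/2009"
  xmlns:xsi="http://www.w3.org/2001/XMLSchema-instance" version="0.9">
  <otus id="ol1"><otu id="o1" label="a"/><otu id="o2" label="b"/></otus>
  <trees id="g1" otus="ol1">
    <tree id="t1" xsi:type="nex:FloatTree">
      <node id="n1" otu="o1"/><node id="n2" otu="o2"/><node id="n3"/>
      <edge id="e1" source="n3" target="n1" length="1.0"/>
      <edge id="e2" source="n3" target="n2" length="2.0"/>
    </tree>
  </trees>
</nexml>"""


class TestNexmlReading:
    def test_cross_referenced_pattern(self):
        events = list(NexmlReader(NEXML_DOC).events())
        assert validate_stream(events).valid
        group = next(ev for ev in events
                     if ev.type is EventType.TREE_NETWORK_GROUP
                     and ev.topology is Topology.START)
        assert group.linked_id == "ol1"
        nodes = {ev.id: ev.linked_id for ev in events
                 if ev.type is EventType.NODE
                 and ev.topology is Topology.START}
        assert nodes == {"n1": "o1", "n2": "o2", "n3": None}

    def test_source_ids_reused(self):
        events = list(NexmlReader(NEXML_DOC).events())
        ids = {ev.id for ev in events if ev.id}
        assert {"ol1", "o1", "o2", "g1", "t1", "n1", "e1"} <= ids

    def test_empty_document(self):
        events = list(NexmlReader(
            '<nexml xmlns="http://www.nexml.org/2009"/>').events())
        assert [ev.type for ev in events] == [EventType.DOCUMENT,
                                              EventType.DOCUMENT]

    def test_duplicate_id_rejected(self):
        bad = NEXML_DOC.replace('id="o2"', 'id="o1"')
        with pytest.raises(FormatError) as err:
            list(NexmlReader(bad).events())
        assert err.value.code == "DUPLICATE_ID"

    def test_dangling_otu_reference_rejected(self):
        bad = NEXML_DOC.replace('otu="o2"', 'otu="missing"')
        with pytest.raises(FormatError) as err:
            list(NexmlReader(bad).events())
        assert err.value.code == "DANGLING_REFERENCE"

    def test_nested_resource_meta_preserves_order(self):
        doc = """<nexml xmlns="http://www.nexml.org/2009"
          xmlns:xsi="http://www.w3.org/2001/XMLSchema-instance"
          xmlns:ex="http://example.com/ns/">
          <meta id="m1" xsi:type="nex:ResourceMeta" rel="ex:about">
            <meta id="m2" xsi:type="nex:LiteralMeta" property="ex:first"
                  content="1" datatype="xsd:integer"
                  xmlns:xsd="http://www.w3.org/2001/XMLSchema#"/>
            <meta id="m3" xsi:type="nex:LiteralMeta" property="ex:second"
                  content="two"/>
          </meta>
        </nexml>"""
        events = list(NexmlReader(doc).events())
        adapter = events_to_adapter(events)
        tree = build_meta_tree(adapter.document_metadata)
        assert tree[0].kind == "resource"
        assert [(c.predicate.local_part, c.value)
                for c in tree[0].children] == [("first", 1), ("second", "two")]


class TestNexmlLosslessness:
    @pytest.mark.parametrize("seed", range(6))
    def test_full_stream_identity(self, seed):
        """read(write(stream)) == stream, including metadata depth 5,
        networks, custom token sets and sets."""
        spec = FixtureSpec(seed=seed, n_otu_lists=2, n_otus=3, n_matrices=2,
                           n_sequences=3, seq_length=6, n_trees=1,
                           n_networks=1, metadata_depth=5,
                           metadata_per_element=2, set_count=2)
        events = generate_fixture(spec)
        text, result = NexmlWriter().write_to_string(
            events_to_adapter(events))
        assert len(result.warnings) == 0  # lossless: nothing dropped
        assert list(NexmlReader(text).events()) == events

    def test_metadata_depth_preserved_structurally(self):
        spec = FixtureSpec(seed=11, metadata_depth=4, metadata_per_element=1,
                           n_trees=0, n_matrices=0, n_otus=1)
        events = generate_fixture(spec)
        text, _ = NexmlWriter().write_to_string(events_to_adapter(events))
        root = ET.fromstring(text)

        def max_meta_depth(elem, depth=0):
            metas = [c for c in elem
                     if c.tag.endswith("meta")]
            if not metas:
                return depth
            return max(max_meta_depth(m, depth + 1) for m in metas)

        original_depth = _max_annotation_depth(
            build_meta_tree(events_to_adapter(events).otu_lists[0].metadata))
        assert max_meta_depth(root) >= original_depth

    def test_string_key_only_literal_survives(self):
        from phylostream.formats.fasta import FastaReader
        doc = events_to_adapter(FastaReader(">s1 a description\nAC").events())
        text, _ = NexmlWriter().write_to_string(doc)
        events = list(NexmlReader(text).events())
        infos = [ev.payload for ev in events
                 if ev.type is EventType.LITERAL_META
                 and ev.topology is Topology.START]
        assert [(i.predicate, i.string_key) for i in infos] == \
            [(None, "description")]

    def test_cell_style_option_reads_back(self):
        spec = FixtureSpec(seed=4, n_otus=2, n_sequences=2, seq_length=5)
        events = generate_fixture(spec)
        doc = events_to_adapter(events)
        text, _ = NexmlWriter().write_to_string(doc, cell_style=True)
        assert "<cell" in text
        doc2 = events_to_adapter(NexmlReader(text).events())
        t1 = [doc.matrices[0].sequence_tokens(s)
              for s in doc.matrices[0].sequence_ids()]
        t2 = [doc2.matrices[0].sequence_tokens(s)
              for s in doc2.matrices[0].sequence_ids()]
        assert t1 == t2


def _max_annotation_depth(nodes, depth=0):
    if not nodes:
        return depth
    return max(_max_annotation_depth(n.children, depth + 1) for n in nodes)


PHYLOXML_DOC = """<phyloxml xmlns="http://www.phylogeny.org/phyloXML"
  xmlns:ex="http://example.com/someOntology/">
 <phylogeny rooted="true">
  <clade>
   <clade branch_length="1.0">
    <name>a</name>
    <taxonomy><id>9606</id><scientific_name>human</scientific_name></taxonomy>
    <confidence type="bootstrap">95</confidence>
    <property ref="ex:support" applies_to="parent_branch"
              datatype="xsd:double">0.95</property>
   </clade>
   <clade branch_length="2.0"><name>b</name></clade>
  </clade>
 </phylogeny>
</phyloxml>"""


class TestPhyloXmlReading:
    def test_confidence_maps_to_predicate_with_type_key(self):
        doc = events_to_adapter(PhyloXmlReader(PHYLOXML_DOC).events())
        tree = doc.tree_network_groups[0].members[0]
        node_a = next(tree.nodes[n] for n in tree.node_ids()
                      if tree.nodes[n].start.label == "a")
        metas = build_meta_tree(node_a.content)
        confidence = [m for m in metas
                      if m.predicate and
                      m.predicate.local_part == "confidence"]
        assert confidence[0].string_key == "bootstrap"
        assert confidence[0].value == 95.0

    def test_taxonomy_becomes_nested_resource(self):
        doc = events_to_adapter(PhyloXmlReader(PHYLOXML_DOC).events())
        tree = doc.tree_network_groups[0].members[0]
        node_a = next(tree.nodes[n] for n in tree.node_ids()
                      if tree.nodes[n].start.label == "a")
        metas = build_meta_tree(node_a.content)
        taxonomy = [m for m in metas if m.kind == "resource"][0]
        assert taxonomy.rel.local_part == "taxonomy"
        assert [(c.predicate.local_part, c.value)
                for c in taxonomy.children] == [
            ("taxonomy/id", "9606"),
            ("taxonomy/scientific_name", "human")]

    def test_property_applies_to_parent_branch(self):
        doc = events_to_adapter(PhyloXmlReader(PHYLOXML_DOC).events())
        tree = doc.tree_network_groups[0].members[0]
        edge_to_a = next(
            e for e in tree.edges
            if tree.nodes[e.start.payload.target_id].start.label == "a")
        metas = build_meta_tree(edge_to_a.content)
        assert [(m.predicate.local_part, m.value) for m in metas] == \
            [("support", 0.95)]

    def test_clade_relation_yields_network(self):
        doc_text = """<phyloxml xmlns="http://www.phylogeny.org/phyloXML">
 <phylogeny rooted="true">
  <clade>
   <clade id_source="x"><name>a</name></clade>
   <clade><clade id_source="y"><name>b</name></clade>
          <clade><name>c</name></clade></clade>
  </clade>
  <clade_relation id_ref_0="x" id_ref_1="y" type="horizontal_transfer"/>
 </phylogeny>
</phyloxml>"""
        doc = events_to_adapter(PhyloXmlReader(doc_text).events())
        member = doc.tree_network_groups[0].members[0]
        assert member.is_network
        # tree edges + one extra
        assert len(member.edges) == len(member.nodes) - 1 + 1

    def test_dangling_clade_relation_rejected(self):
        bad = """<phyloxml xmlns="http://www.phylogeny.org/phyloXML">
 <phylogeny rooted="true"><clade><name>a</name></clade>
  <clade_relation id_ref_0="no" id_ref_1="pe" type="x"/>
 </phylogeny></phyloxml>"""
        with pytest.raises(FormatError):
            list(PhyloXmlReader(bad).events())


class TestPhyloXmlWriting:
    def test_round_trip_identity_on_mapped_subset(self):
        events = list(PhyloXmlReader(PHYLOXML_DOC).events())
        doc = events_to_adapter(events)
        text, result = PhyloXmlWriter().write_to_string(doc)
        assert list(PhyloXmlReader(text).events()) == events
        assert len(result.warnings) == 0

    def test_drop_strategy_removes_custom_subtrees_with_warning(self):
        spec = FixtureSpec(seed=5, n_otus=2, n_sequences=0, n_matrices=0,
                           seq_length=0, n_trees=1, metadata_depth=3,
                           metadata_per_element=1)
        doc = events_to_adapter(generate_fixture(spec))
        text, result = PhyloXmlWriter().write_to_string(
            doc, strategy=DROP_NON_REPRESENTABLE)
        assert result.warnings.count("METADATA_DROPPED") >= 1
        assert "<property" not in text

    def test_flatten_strategy_writes_leaf_properties(self):
        spec = FixtureSpec(seed=5, n_otus=2, n_sequences=0, n_matrices=0,
                           seq_length=0, n_trees=1, metadata_depth=3,
                           metadata_per_element=1)
        doc = events_to_adapter(generate_fixture(spec))
        text, result = PhyloXmlWriter().write_to_string(
            doc, strategy=FLATTEN_LEAVES_TO_PROPERTIES)
        assert "<property" in text
        assert result.warnings.count("HIERARCHY_FLATTENED") >= 1
        # output parses back
        assert validate_stream(PhyloXmlReader(text).events()).valid

    def test_document_without_trees_rejected(self):
        from phylostream.formats.fasta import FastaReader
        doc = events_to_adapter(FastaReader(">a\nAC").events())
        with pytest.raises(WriteError) as err:
            PhyloXmlWriter().write_to_string(doc)
        assert err.value.code == "NO_WRITABLE_CONTENT"

    def test_branch_lengths_survive_to_1e9(self):
        events = list(PhyloXmlReader(PHYLOXML_DOC).events())
        doc = events_to_adapter(events)
        text, _ = PhyloXmlWriter().write_to_string(doc)
        doc2 = events_to_adapter(PhyloXmlReader(text).events())
        lengths1 = sorted(e.start.payload.length
                          for m in doc.tree_network_groups[0].members
                          for e in m.edges)
        lengths2 = sorted(e.start.payload.length
                          for m in doc2.tree_network_groups[0].members
                          for e in m.edges)
        assert all(abs(a - b) < 1e-9 for a, b in zip(lengths1, lengths2))
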