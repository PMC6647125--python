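"""Newick engine: tokenizer, parser, hot comments, eNewick, writer."""

import random

import dendropy
import pytest

from phylostream import (EventType, FormatError, IdSource, Topology,
                         WarningLog, build_meta_tree, events_to_adapter,
                         validate_stream)
from phylostream.formats.newick import (NewickReader, NewickWriter,
                                        parse_hot_comment, parse_newick,
                                        resolve_enewick,
                                        serialize_tree_newick,
                                        tokenize_newick)
from treecanon import canonical_from_adapter, canonical_from_dendropy


class TestTokenizer:
    def test_structural_tokens(self):
        kinds = [(t.kind, t.value) for t in tokenize_newick("(a,b);")]
        assert kinds == [("punct", "("), ("name", "a"), ("punct", ","),
                         ("name", "b"), ("punct", ")"), ("punct", ";")]

    def test_quote_escaping(self):
        tokens = tokenize_newick("'x ''y'''")
        assert [(t.kind, t.value) for t in tokens] == [("name", "x 'y'")]

    def test_underscores_become_spaces_unquoted_only(self):
        assert tokenize_newick("a_b")[0].value == "a b"
        assert tokenize_newick("'a_b'")[0].value == "a_b"

    def test_comment_bound_between_name_and_colon(self):
        tokens = tokenize_newick("(a[&v=1]:2)")
        assert [t.kind for t in tokens] == ["punct", "name", "comment",
                                            "punct", "name", "punct"]

    def test_unterminated_inputs_error(self):
        with pytest.raises(FormatError):
            tokenize_newick("(a[comment")
        with pytest.raises(FormatError):
            tokenize_newick("'unclosed")


class TestParser:
    def test_hand_derived_event_sequence(self):
        events = parse_newick(tokenize_newick("(a:1,b:2)r:0.5;"), IdSource())
        nodes = [(ev.label) for ev in events
                 if ev.type is EventType.NODE and ev.topology is Topology.START]
        assert nodes == ["a", "b", "r"]
        edges = [(ev.payload.length) for ev in events
                 if ev.type is EventType.EDGE and ev.topology is Topology.START]
        assert edges == [1.0, 2.0]
        roots = [ev.payload for ev in events
                 if ev.type is EventType.ROOT_EDGE
                 and ev.topology is Topology.START]
        assert len(roots) == 1 and roots[0].length == 0.5
        # children precede parents; edges follow both endpoints
        seen = set()
        for ev in events:
            if ev.type is EventType.NODE and ev.topology is Topology.START:
                seen.add(ev.id)
            if ev.type is EventType.EDGE and ev.topology is Topology.START:
                assert ev.payload.source_id in seen
                assert ev.payload.target_id in seen

    def test_degenerate_tree_single_root(self):
        events = parse_newick(tokenize_newick(";"), IdSource())
        nodes = [ev for ev in events if ev.type is EventType.NODE
                 and ev.topology is Topology.START]
        edges = [ev for ev in events if ev.type is EventType.EDGE]
        assert len(nodes) == 1 and nodes[0].label is None and not edges

    @pytest.mark.parametrize("bad", ["((a,b);", "(a:1:2);", "(a,b))" ";"])
    def test_malformed_strings_error(self, bad):
        with pytest.raises(FormatError):
            parse_newick(tokenize_newick(bad), IdSource())


class TestHotComments:
    def test_nhx_entries_mapped_to_phyloxml_predicates(self):
        hc = parse_hot_comment("&&NHX:S=human:B=95")
        assert hc.kind == "NHX"
        from phylostream.formats.newick import hot_comment_meta
        nodes = hot_comment_meta(hc)
        assert nodes[0].predicate.local_part == "taxonomy/scientific_name"
        assert nodes[0].value == "human"
        assert nodes[1].predicate.local_part == "confidence"
        assert nodes[1].value == 95

    def test_key_value_entries_with_array(self):
        hc = parse_hot_comment("&height=1.0,range={0.5,1.5}")
        assert hc.kind == "KEY_VALUE"
        assert hc.entries == [("height", 1.0), ("range", [0.5, 1.5])]

    def test_plain_text_degrades_to_comment(self):
        hc = parse_hot_comment("just a remark")
        assert hc.kind == "PLAIN" and not hc.entries

    def test_attachment_follows_colon_rule(self):
        assert parse_hot_comment("&x=1", after_colon=False).attachment == "node"
        assert parse_hot_comment("&x=1", after_colon=True).attachment == "branch"

    def test_node_and_branch_metadata_land_on_node_and_edge(self):
        events = parse_newick(
            tokenize_newick("(a[&support=0.95]:[&rate=2.0]1.0)r;"),
            IdSource())
        doc = _wrap_tree(events)
        tree = doc.tree_network_groups[0].members[0]
        node_meta = [n for nid in tree.node_ids()
                     for n in build_meta_tree(tree.nodes[nid].content)]
        assert [(n.string_key, n.value) for n in node_meta] == [
            ("support", 0.95)]
        edge_meta = build_meta_tree(tree.edges[0].content)
        assert [(n.string_key, n.value) for n in edge_meta] == [("rate", 2.0)]


def _wrap_tree(tree_events):
    from phylostream.events import end, start
    return events_to_adapter([
        start(EventType.DOCUMENT, "d"),
        start(EventType.TREE_NETWORK_GROUP, "g"),
        *tree_events,
        end(EventType.TREE_NETWORK_GROUP),
        end(EventType.DOCUMENT)])


def random_newick(rng, n_tips):
    tips = [f"t{i}" for i in range(n_tips)]
    rng.shuffle(tips)

    def build(labels):
        if len(labels) == 1:
            return f"{labels[0]}:{round(rng.uniform(0.01, 3.0), 6)}"
        split = rng.randrange(1, len(labels))
        left, right = build(labels[:split]), build(labels[split:])
        return f"({left},{right}):{round(rng.uniform(0.01, 3.0), 6)}"

    inner = build(tips)
    # strip the root length half the time
    if rng.random() < 0.5:
        inner = inner.rsplit(":", 1)[0]
    return inner + ";"


class TestOracleAgreement:
    def test_topology_and_lengths_match_dendropy(self):
        """Independent-parser agreement on 200 random trees; branch
        lengths to 1e-12."""
        rng = random.Random(2024)
        for _ in range(200):
            text = random_newick(rng, rng.randrange(2, 9))
            doc = events_to_adapter(NewickReader(text).events())
            ours = canonical_from_adapter(
                doc.tree_network_groups[0].members[0])
            dtree = dendropy.Tree.get(data=text, schema="newick",
                                      suppress_internal_node_taxa=True)
            theirs = canonical_from_dendropy(dtree)
            assert ours == theirs

    def test_write_parse_write_is_fixed_point(self):
        """Second and third serializations byte-identical on 200 trees."""
        rng = random.Random(7)
        for _ in range(200):
            text = random_newick(rng, rng.randrange(2, 9))
            doc1 = events_to_adapter(NewickReader(text).events())
            out1, _ = NewickWriter().write_to_string(doc1)
            doc2 = events_to_adapter(NewickReader(out1).events())
            out2, _ = NewickWriter().write_to_string(doc2)
            assert out1 == out2


class TestENewick:
    NETWORK = "((a,(b)#H1),(#H1,c));"

    def test_merge_produces_indegree_two_node(self):
        doc = events_to_adapter(NewickReader(self.NETWORK).events())
        member = doc.tree_network_groups[0].members[0]
        assert member.is_network
        indeg = {}
        for edge in member.edges:
            indeg[edge.start.payload.target_id] = \
                indeg.get(edge.start.payload.target_id, 0) + 1
        assert max(indeg.values()) == 2

    def test_merge_preserves_edges_and_reduces_nodes(self):
        # brute-force count on the unmerged tree as oracle
        tree_events = parse_newick(tokenize_newick(self.NETWORK), IdSource())
        nodes_before = sum(1 for ev in tree_events
                           if ev.type is EventType.NODE
                           and ev.topology is Topology.START)
        edges_before = sum(1 for ev in tree_events
                           if ev.type is EventType.EDGE
                           and ev.topology is Topology.START)
        merged = resolve_enewick(tree_events)
        nodes_after = sum(1 for ev in merged
                          if ev.type is EventType.NODE
                          and ev.topology is Topology.START)
        edges_after = sum(1 for ev in merged
                          if ev.type is EventType.EDGE
                          and ev.topology is Topology.START)
        assert edges_after == edges_before
        assert nodes_after == nodes_before - 1  # one tag, two occurrences

    def test_no_tags_is_identity(self):
        tree_events = parse_newick(tokenize_newick("(a,b);"), IdSource())
        assert resolve_enewick(tree_events) is tree_events

    def test_crosslink_type_recorded(self):
        doc = events_to_adapter(
            NewickReader("((a,(b)#LGT1),(#LGT1,c));").events())
        member = doc.tree_network_groups[0].members[0]
        values = []
        for nid in member.node_ids():
            for node in build_meta_tree(member.nodes[nid].content):
                if node.string_key == "crosslink_type":
                    values.append(node.value)
        assert values == ["LGT"]

    def test_dangling_tag_warns(self):
        log = WarningLog()
        tree_events = parse_newick(tokenize_newick("((a)#H1,b);"), IdSource())
        resolve_enewick(tree_events, log)
        assert log.count("DANGLING_HYBRID") == 1

    def test_network_round_trip_through_writer(self):
        doc = events_to_adapter(NewickReader(self.NETWORK).events())
        text, _ = NewickWriter().write_to_string(doc)
        doc2 = events_to_adapter(NewickReader(text).events())
        m1 = doc.tree_network_groups[0].members[0]
        m2 = doc2.tree_network_groups[0].members[0]
        assert m2.is_network
        assert len(m2.nodes) == len(m1.nodes)
        assert len(m2.edges) == len(m1.edges)


class TestWriter:
    def test_node_metadata_written_before_colon(self):
        doc = events_to_adapter(
            NewickReader("(a[&support=0.95]:1.0)r;").events())
        log = WarningLog()
        text = serialize_tree_newick(doc.tree_network_groups[0].members[0],
                                     log)
        assert "a[&support=0.95]:" in text

    def test_hierarchical_metadata_flattened_to_leaves(self, rich_adapter):
        member = next(m for g in rich_adapter.tree_network_groups
                      for m in g.members if not m.is_network)
        log = WarningLog()
        text = serialize_tree_newick(member, log)
        assert text.endswith(";")
        assert log.count("HIERARCHY_FLATTENED") >= 1

    def test_style_none_drops_all_annotations_with_warnings(self):
        doc = events_to_adapter(
            NewickReader("(a[&support=0.95]:1.0,b[&x=1]:2.0);").events())
        log = WarningLog()
        text = serialize_tree_newick(doc.tree_network_groups[0].members[0],
                                     log, metadata_style="NONE")
        assert "[" not in text
        assert log.count("METADATA_DROPPED") == 2

    def test_multiple_trees_one_group(self):
        events = list(NewickReader("(a,b);(c,d);").events())
        groups = [ev for ev in events
                  if ev.type is EventType.TREE_NETWORK_GROUP
                  and ev.topology is Topology.START]
        trees = [ev for ev in events if ev.type is EventType.TREE
                 and ev.topology is Topology.START]
        assert len(groups) == 1 and len(trees) == 2
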