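"""Seeded synthetic-document generator.

Produces grammar-valid event streams covering every content kind the
library models: OTU lists, alignments with token sets and character
definitions, trees, eNewick-style networks, element sets, and metadata
trees of configurable depth attached throughout.  Identical seeds and
parameters yield identical streams, which makes the generator the fixture
corpus for all round-trip, conversion and validation tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .events import (EdgeInfo, Event, EventType, IdSource, end, sole, start)
from .meta import MetaNode, Predicate, emit_meta_tree, xsd

EXAMPLE_NS = "http://example.com/someOntology/"
CUSTOM_XML_NS = "{http://example.com/customXml}"


@dataclass
class FixtureSpec:
    """Parameters of one synthetic document."""

    seed: int = 0
    n_otu_lists: int = 1
    n_otus: int = 5
    n_matrices: int = 1
    n_sequences: int = 5
    seq_length: int = 20
    n_trees: int = 1
    n_networks: int = 0
    metadata_depth: int = 0
    metadata_per_element: int = 0
    set_count: int = 0
    token_alphabet: str = "ACGT"


def _predicate(local: str) -> Predicate:
    return Predicate(EXAMPLE_NS, local, prefix="ex")


class _Generator:
    def __init__(self, spec: FixtureSpec):
        self.spec = spec
        self.rng = random.Random(spec.seed)
        self.ids = IdSource()
        self.meta_counter = 0

    # -- metadata -----------------------------------------------------------

    def _leaf_value(self) -> tuple[object, Predicate | None]:
        choice = self.rng.randrange(5)
        if choice == 0:
            return round(self.rng.uniform(0, 1), 6), xsd("double")
        if choice == 1:
            return self.rng.randrange(1000), xsd("integer")
        if choice == 2:
            return self.rng.random() < 0.5, xsd("boolean")
        if choice == 3:
            return [round(self.rng.uniform(0, 2), 4) for _ in range(2)], None
        return f"value{self.rng.randrange(1000)}", None

    def _meta_tree(self, depth: int) -> MetaNode:
        self.meta_counter += 1
        if depth <= 1:
            value, datatype = self._leaf_value()
            if datatype is None and isinstance(value, list):
                from .meta import DATATYPE_NAMESPACE
                datatype = Predicate(DATATYPE_NAMESPACE, "array", prefix="pdt")
            if self.rng.random() < 0.5:
                return MetaNode(kind="literal",
                                predicate=_predicate(
                                    f"term{self.meta_counter}"),
                                datatype=datatype, value=value)
            return MetaNode(kind="literal",
                            string_key=f"key{self.meta_counter}",
                            datatype=datatype, value=value)
        children = [self._meta_tree(depth - 1)
                    for _ in range(self.rng.randrange(1, 3))]
        href = (f"http://example.com/resource/{self.meta_counter}"
                if self.rng.random() < 0.5 else None)
        return MetaNode(kind="resource",
                        rel=_predicate(f"rel{self.meta_counter}"),
                        href=href, children=children)

    def _xml_meta(self) -> MetaNode:
        self.meta_counter += 1
        events = [
            ("start", f"{CUSTOM_XML_NS}note", {"idx": str(self.meta_counter)}),
            ("chars", f"free text {self.meta_counter}"),
            ("end", f"{CUSTOM_XML_NS}note"),
        ]
        return MetaNode(kind="literal",
                        predicate=_predicate(f"xml{self.meta_counter}"),
                        content_form="xml", value=events)

    def metadata(self, depth: int | None = None) -> list[Event]:
        spec = self.spec
        if spec.metadata_per_element <= 0:
            return []
        depth = spec.metadata_depth if depth is None else depth
        if depth <= 0:
            return []
        nodes = []
        for i in range(spec.metadata_per_element):
            if depth >= 2 and i == 0 and self.rng.random() < 0.3:
                nodes.append(self._xml_meta())
            else:
                nodes.append(self._meta_tree(
                    self.rng.randrange(1, depth + 1)))
        return emit_meta_tree(nodes, self.ids)

    # -- content ------------------------------------------------------------

    def otu_list(self, index: int) -> tuple[list[Event], list[tuple[str, str]]]:
        spec = self.spec
        events = [start(EventType.OTU_LIST, self.ids.new(),
                        label=f"taxa{index + 1}")]
        events.extend(self.metadata())
        otus: list[tuple[str, str]] = []
        for i in range(spec.n_otus):
            otu_id = self.ids.new()
            label = f"taxon{index + 1}_{i + 1}"
            otus.append((otu_id, label))
            events.append(start(EventType.OTU, otu_id, label=label))
            if i == 0:
                events.extend(self.metadata())
            events.append(end(EventType.OTU))
        for s in range(spec.set_count):
            members = [otu_id for otu_id, _ in
                       otus[s % max(1, len(otus)):][:2]]
            events.append(start(EventType.OTU_SET, self.ids.new(),
                                label=f"otuset{s + 1}", payload=members))
            events.append(end(EventType.OTU_SET))
        events.append(end(EventType.OTU_LIST))
        return events, otus

    def matrix(self, index: int, otu_list_id: str | None,
               otus: list[tuple[str, str]]) -> list[Event]:
        spec = self.spec
        events = [start(EventType.ALIGNMENT, self.ids.new(),
                        label=f"matrix{index + 1}", linked_id=otu_list_id)]
        events.extend(self.metadata())
        if spec.seq_length > 0:
            tokens = {c: c for c in spec.token_alphabet}
            events.append(start(
                EventType.TOKEN_SET_DEFINITION, self.ids.new(), label="DNA",
                payload={"intervals": [(0, spec.seq_length)],
                         "tokens": tokens}))
            events.append(end(EventType.TOKEN_SET_DEFINITION))
        if spec.set_count > 0 and spec.seq_length > 0:
            events.append(start(EventType.CHARACTER_DEFINITION,
                                self.ids.new(), label="first_site",
                                payload={"index": 0}))
            events.append(end(EventType.CHARACTER_DEFINITION))
        for i in range(spec.n_sequences):
            if i < len(otus):
                otu_id, label = otus[i]
            else:
                otu_id, label = None, f"seq{index + 1}_{i + 1}"
            seq = [self.rng.choice(spec.token_alphabet)
                   for _ in range(spec.seq_length)]
            events.append(start(EventType.SEQUENCE, self.ids.new(),
                                label=label, linked_id=otu_id))
            if i == 0:
                events.extend(self.metadata())
            if seq:
                events.append(sole(EventType.SEQUENCE_TOKENS, payload=seq))
            events.append(end(EventType.SEQUENCE))
        for s in range(spec.set_count):
            if spec.seq_length <= 0:
                break
            width = max(1, spec.seq_length // (s + 2))
            begin = min(s, spec.seq_length - 1)
            stop = min(begin + width, spec.seq_length)
            events.append(start(EventType.CHARACTER_SET, self.ids.new(),
                                label=f"charset{s + 1}",
                                payload=[(begin, stop)]))
            events.append(end(EventType.CHARACTER_SET))
        events.append(end(EventType.ALIGNMENT))
        return events

    def tree(self, index: int, otus: list[tuple[str, str]],
             network: bool = False) -> list[Event]:
        """Random binary tree over the OTUs; networks add one crosslink
        edge, giving a node in-degree two."""
        etype = EventType.NETWORK if network else EventType.TREE
        events = [start(etype, self.ids.new(),
                        label=(f"network{index + 1}" if network
                               else f"tree{index + 1}"))]
        events.extend(self.metadata())
        tips = []
        for otu_id, label in otus:
            node_id = self.ids.new()
            events.append(start(EventType.NODE, node_id, label=label,
                                linked_id=otu_id))
            if not tips:
                events.extend(self.metadata())
            events.append(end(EventType.NODE))
            tips.append(node_id)
        if not tips:
            node_id = self.ids.new()
            events.append(start(EventType.NODE, node_id))
            events.append(end(EventType.NODE))
            events.append(end(etype))
            return events
        active = list(tips)
        edges: list[tuple[str, str]] = []
        while len(active) > 1:
            i = self.rng.randrange(len(active))
            a = active.pop(i)
            j = self.rng.randrange(len(active))
            b = active.pop(j)
            parent = self.ids.new()
            events.append(start(EventType.NODE, parent))
            events.append(end(EventType.NODE))
            edges.append((parent, a))
            edges.append((parent, b))
            active.append(parent)
        root = active[0]
        first_edge = True
        for source, target in edges:
            length = round(self.rng.uniform(0.01, 2.0), 6)
            events.append(start(EventType.EDGE, self.ids.new(),
                                payload=EdgeInfo(source, target, length)))
            if first_edge:
                events.extend(self.metadata())
                first_edge = False
            events.append(end(EventType.EDGE))
        if network and len(tips) >= 2:
            # one extra edge: last internal node to an unrelated tip
            target = tips[0]
            sources = [s for s, t in edges if t != target and s != target]
            if sources:
                events.append(start(
                    EventType.EDGE, self.ids.new(),
                    payload=EdgeInfo(sources[-1], target,
                                     round(self.rng.uniform(0.01, 2.0), 6))))
                events.append(end(EventType.EDGE))
        events.append(end(etype))
        return events


def generate_fixture(spec: FixtureSpec) -> list[Event]:
    """Generate one synthetic document event stream from ``spec``.

    The output always satisfies :func:`~phylostream.events.validate_stream`,
    links sequences and tree tips to their OTUs, and is byte-deterministic
    in (seed, parameters).
    """
    gen = _Generator(spec)
    events: list[Event] = [start(EventType.DOCUMENT, gen.ids.new())]
    events.extend(gen.metadata())

    all_otus: list[list[tuple[str, str]]] = []
    otu_list_ids: list[str] = []
    for i in range(spec.n_otu_lists):
        sub, otus = gen.otu_list(i)
        events.extend(sub)
        all_otus.append(otus)
        otu_list_ids.append(sub[0].id)

    for i in range(spec.n_matrices):
        list_index = i % len(all_otus) if all_otus else None
        events.extend(gen.matrix(
            i,
            otu_list_ids[list_index] if list_index is not None else None,
            all_otus[list_index] if list_index is not None else []))

    if spec.n_trees or spec.n_networks:
        group_id = gen.ids.new()
        linked = otu_list_ids[0] if otu_list_ids else None
        events.append(start(EventType.TREE_NETWORK_GROUP, group_id,
                            linked_id=linked))
        events.extend(gen.metadata())
        member_ids = []
        otus = all_otus[0] if all_otus else []
        for i in range(spec.n_trees):
            sub = gen.tree(i, otus)
            events.extend(sub)
            member_ids.append(sub[0].id)
        for i in range(spec.n_networks):
            sub = gen.tree(i, otus, network=True)
            events.extend(sub)
            member_ids.append(sub[0].id)
        for s in range(spec.set_count):
            if not member_ids:
                break
            events.append(start(EventType.TREE_NETWORK_SET, gen.ids.new(),
                                label=f"treeset{s + 1}",
                                payload=member_ids[:1 + s % len(member_ids)]))
            events.append(end(EventType.TREE_NETWORK_SET))
        events.append(end(EventType.TREE_NETWORK_GROUP))

    events.append(end(EventType.DOCUMENT))
    return events


def fixture_corpus(n: int = 20, base_seed: int = 0) -> list[FixtureSpec]:
    """A spread of specs spanning all content kinds: plain alignments,
    annotated documents, deep metadata, trees, networks and sets."""
    specs = []
    for i in range(n):
        specs.append(FixtureSpec(
            seed=base_seed + i,
            n_otu_lists=1 + i % 2,
            n_otus=2 + i % 4,
            n_matrices=1 + i % 2,
            n_sequences=2 + i % 4,
            seq_length=(0 if i % 7 == 3 else 8 + i % 13),
            n_trees=i % 3,
            n_networks=i % 4 // 3,
            metadata_depth=i % 6,
            metadata_per_element=(0 if i % 5 == 0 else 1 + i % 2),
            set_count=i % 3,
        ))
    return specs
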