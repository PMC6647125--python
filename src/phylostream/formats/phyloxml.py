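"""phyloXML reading and writing.

phyloXML stores trees (and, via ``clade_relation`` tags, networks) with a
fixed vocabulary of metadata elements.  To fit that vocabulary into the
RDF-style internal model, every predefined element is identified by an
internal predicate (namespace
``https://phylostream.example/predicates/phyloxml/`` plus the element
path, e.g. ``taxonomy/id``), and that mapping is applied in both
directions.  Free annotations use ``property`` tags (flat key/value with
an XSD datatype and an ``applies_to`` scope) and custom XML in foreign
namespaces, both of which are read as literal metadata.

Custom hierarchical annotation trees cannot be represented.  On writing a
translation strategy decides their fate: ``DROP_NON_REPRESENTABLE``
discards whole non-mappable subtrees, ``FLATTEN_LEAVES_TO_PROPERTIES``
keeps each leaf literal as a property tag; both log one warning per
dropped annotation.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from typing import IO, Iterator, Optional

from ..adapters import DocumentAdapter, TreeOrNetworkAdapter, WarningLog
from ..events import (EdgeInfo, Event, EventType, FormatError, WriteError,
                      end, start)
from ..meta import (MetaNode, PHYLOXML_PREDICATE_NAMESPACE, Predicate,
                    ROOTED_PREDICATE, build_meta_tree, emit_meta_tree,
                    leaf_literals, parse_literal, xsd)
from ._base import EventReader, EventWriter, WriteResult
from .nexml import _NamespaceTable, _local, _split_tag

PHYLOXML_NS = "http://www.phylogeny.org/phyloXML"

DROP_NON_REPRESENTABLE = "DROP_NON_REPRESENTABLE"
FLATTEN_LEAVES_TO_PROPERTIES = "FLATTEN_LEAVES_TO_PROPERTIES"


def px(path: str) -> Predicate:
    return Predicate(PHYLOXML_PREDICATE_NAMESPACE, path, prefix="px")


#: resource-level predefined elements and the literal children they carry
_RESOURCE_CHILDREN = {
    "taxonomy": ["id", "code", "scientific_name", "common_name", "rank"],
    "sequence": ["symbol", "accession", "name", "mol_seq"],
    "events": ["type", "duplications", "speciations", "losses"],
}
_NUMERIC_CHILDREN = {"duplications", "speciations", "losses"}


class PhyloXmlReader(EventReader):
    format_id = "phyloxml"

    def events(self) -> Iterator[Event]:
        from .nexml import _parse_with_namespaces
        root, ns = _parse_with_namespaces(self.stream)
        ns_uri, local = _split_tag(root.tag)
        if local != "phyloxml" or ns_uri not in (None, PHYLOXML_NS):
            raise FormatError("root element is not phyloXML",
                              code="PHYLOXML_SYNTAX")
        self._ns = ns
        yield start(EventType.DOCUMENT, self.ids.new())
        phylogenies = [c for c in root if _local(c.tag) == "phylogeny"]
        if phylogenies:
            yield start(EventType.TREE_NETWORK_GROUP, self.ids.new())
            for phylogeny in phylogenies:
                yield from self._read_phylogeny(phylogeny)
            yield end(EventType.TREE_NETWORK_GROUP)
        yield end(EventType.DOCUMENT)

    def _read_phylogeny(self, elem: ET.Element) -> Iterator[Event]:
        relations = [c for c in elem if _local(c.tag) == "clade_relation"]
        etype = EventType.NETWORK if relations else EventType.TREE
        name = next((c.text for c in elem if _local(c.tag) == "name"), None)

        tree_meta: list[MetaNode] = []
        rooted = elem.get("rooted")
        if rooted is not None:
            tree_meta.append(MetaNode(kind="literal",
                                      predicate=ROOTED_PREDICATE,
                                      string_key="rooted",
                                      value=rooted == "true"))
        for child in elem:
            if _local(child.tag) == "property":
                node, _scope = self._property_meta(child)
                tree_meta.append(node)

        yield start(etype, self.ids.new(), label=name)
        yield from emit_meta_tree(tree_meta, self.ids)

        root_clade = next((c for c in elem if _local(c.tag) == "clade"), None)
        self._id_sources: dict[str, str] = {}
        node_events: list[Event] = []
        edge_events: list[Event] = []

        def walk(clade: ET.Element, parent_id: Optional[str]) -> None:
            node_id = self.ids.new()
            id_source = clade.get("id_source")
            if id_source:
                self._id_sources[id_source] = node_id
            label = None
            branch_length = clade.get("branch_length")
            node_meta: list[MetaNode] = []
            branch_meta: list[MetaNode] = []
            children = []
            for child in clade:
                kind = _local(child.tag)
                tag_ns = _split_tag(child.tag)[0]
                if tag_ns not in (None, PHYLOXML_NS):
                    node_meta.append(self._custom_xml_meta(child))
                elif kind == "name":
                    label = child.text
                elif kind == "branch_length":
                    branch_length = child.text
                elif kind == "confidence":
                    node_meta.append(MetaNode(
                        kind="literal", predicate=px("confidence"),
                        string_key=child.get("type"),
                        datatype=xsd("double"),
                        value=float(child.text)))
                elif kind in _RESOURCE_CHILDREN:
                    node_meta.append(self._resource_meta(kind, child))
                elif kind == "property":
                    node, scope = self._property_meta(child)
                    (branch_meta if scope == "parent_branch"
                     else node_meta).append(node)
                    if scope not in ("node", "parent_branch", None):
                        self.warnings.warn(
                            "APPLIES_TO_COERCED", node_id,
                            f"applies_to={scope!r} treated as node")
                elif kind == "clade":
                    children.append(child)
            node_events.append(start(EventType.NODE, node_id, label=label))
            node_events.extend(emit_meta_tree(node_meta, self.ids))
            node_events.append(end(EventType.NODE))
            if parent_id is not None:
                length = float(branch_length) if branch_length is not None \
                    else None
                edge_events.append(start(
                    EventType.EDGE, self.ids.new(),
                    payload=EdgeInfo(parent_id, node_id, length)))
                edge_events.extend(emit_meta_tree(branch_meta, self.ids))
                edge_events.append(end(EventType.EDGE))
            elif branch_length is not None or branch_meta:
                edge_events.append(start(
                    EventType.ROOT_EDGE, self.ids.new(),
                    payload=EdgeInfo(None, node_id,
                                     float(branch_length)
                                     if branch_length is not None else None)))
                edge_events.extend(emit_meta_tree(branch_meta, self.ids))
                edge_events.append(end(EventType.ROOT_EDGE))
            for child in children:
                walk(child, node_id)

        if root_clade is not None:
            walk(root_clade, None)
        yield from node_events
        yield from edge_events
        for relation in relations:
            ref0, ref1 = relation.get("id_ref_0"), relation.get("id_ref_1")
            if ref0 not in self._id_sources or ref1 not in self._id_sources:
                raise FormatError(
                    f"clade_relation references undeclared id_source "
                    f"({ref0!r}, {ref1!r})", code="DANGLING_REFERENCE")
            distance = relation.get("distance")
            rel_meta: list[MetaNode] = []
            if relation.get("type"):
                rel_meta.append(MetaNode(kind="literal",
                                         string_key="crosslink_type",
                                         value=relation.get("type")))
            yield start(EventType.EDGE, self.ids.new(),
                        payload=EdgeInfo(self._id_sources[ref0],
                                         self._id_sources[ref1],
                                         float(distance)
                                         if distance is not None else None))
            yield from emit_meta_tree(rel_meta, self.ids)
            yield end(EventType.EDGE)
        yield end(etype)

    def _resource_meta(self, kind: str, elem: ET.Element) -> MetaNode:
        node = MetaNode(kind="resource", rel=px(kind))
        for child in elem:
            child_kind = _local(child.tag)
            if child_kind in _RESOURCE_CHILDREN[kind] and child.text:
                value: object = child.text
                datatype = None
                if child_kind in _NUMERIC_CHILDREN:
                    value = int(child.text)
                    datatype = xsd("integer")
                node.children.append(MetaNode(
                    kind="literal", predicate=px(f"{kind}/{child_kind}"),
                    datatype=datatype, value=value))
        return node

    def _property_meta(self, elem: ET.Element) -> tuple[MetaNode, str]:
        ref = elem.get("ref", "")
        predicate = self._ns.resolve_curie(ref)
        string_key = None if predicate is not None else (ref or None)
        datatype = None
        dt_attr = elem.get("datatype")
        if dt_attr:
            datatype = self._ns.resolve_curie(dt_attr)
        value = parse_literal((elem.text or "").strip(), datatype)
        node = MetaNode(kind="literal", predicate=predicate,
                        string_key=string_key, datatype=datatype, value=value)
        return node, elem.get("applies_to", "node")

    def _custom_xml_meta(self, elem: ET.Element) -> MetaNode:
        events: list = []

        def walk(e: ET.Element) -> None:
            events.append(("start", e.tag, dict(e.attrib)))
            if e.text and e.text.strip():
                events.append(("chars", e.text))
            for c in e:
                walk(c)
                if c.tail and c.tail.strip():
                    events.append(("chars", c.tail))
            events.append(("end", e.tag))

        walk(elem)
        return MetaNode(kind="literal", predicate=px("customXml"),
                        content_form="xml", value=events)


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------

class PhyloXmlWriter(EventWriter):
    format_id = "phyloxml"

    def write(self, document: DocumentAdapter, stream: IO[str],
              **params) -> WriteResult:
        strategy = params.get("strategy", FLATTEN_LEAVES_TO_PROPERTIES)
        if strategy not in (DROP_NON_REPRESENTABLE,
                            FLATTEN_LEAVES_TO_PROPERTIES):
            raise WriteError(f"unknown strategy {strategy!r}",
                             code="UNKNOWN_STRATEGY")
        result = WriteResult()
        log = result.warnings
        self._ns = _NamespaceTable()

        members = document.all_trees_networks()
        if not members:
            raise WriteError("phyloXML requires at least one tree or network",
                             code="NO_WRITABLE_CONTENT")
        for matrix in document.matrices:
            log.warn("CONTENT_DROPPED", matrix.id,
                     "matrices cannot be written to phyloXML")
        for otu_list in document.otu_lists:
            log.warn("CONTENT_DROPPED", otu_list.id,
                     "OTU lists cannot be written to phyloXML")
        from .fasta import _meta_subtrees, _warn_dropped
        for meta in _meta_subtrees(document.document_metadata):
            _warn_dropped(log, meta, None)

        root = ET.Element("phyloxml")
        for member in members:
            self._write_phylogeny(root, member, strategy, log)
        root.set("xmlns", PHYLOXML_NS)
        for uri, prefix in self._ns.by_uri.items():
            root.set(f"xmlns:{prefix}", uri)
        ET.indent(root)
        stream.write(ET.tostring(root, encoding="unicode") + "\n")
        return result

    def _write_phylogeny(self, root: ET.Element,
                         member: TreeOrNetworkAdapter, strategy: str,
                         log: WarningLog) -> None:
        phylogeny = ET.Element("phylogeny")
        rooted_value = "true"
        properties: list[ET.Element] = []
        for node in build_meta_tree(member.metadata):
            if node.kind == "literal" and node.predicate is not None \
                    and node.predicate.uri == ROOTED_PREDICATE.uri:
                rooted_value = "true" if node.value else "false"
            elif node.kind == "comment":
                continue
            else:
                self._translate_annotation(node, properties, "phylogeny",
                                           strategy, log, member.id)
        phylogeny.set("rooted", rooted_value)
        if member.start.label:
            ET.SubElement(phylogeny, "name").text = member.start.label

        in_edges: dict[str, list] = {}
        children: dict[str, list] = {}
        root_edge = None
        for edge in member.edges:
            info: EdgeInfo = edge.start.payload
            if info.source_id is None:
                root_edge = edge
                continue
            in_edges.setdefault(info.target_id, []).append(edge)
        # spanning tree: the first incoming edge of each node is the tree
        # edge; the rest become clade_relation tags
        extra_edges = []
        for target, edges in in_edges.items():
            tree_edge = edges[0]
            info = tree_edge.start.payload
            children.setdefault(info.source_id, []).append(tree_edge)
            extra_edges.extend(edges[1:])
        roots = [n for n in member.node_ids() if n not in in_edges]
        if not roots:
            raise WriteError("tree without a root cannot be written",
                             code="NO_WRITABLE_CONTENT")
        id_sources: dict[str, str] = {}

        def write_clade(node_id: str, parent: ET.Element,
                        edge) -> None:
            node = member.nodes[node_id]
            clade = ET.SubElement(parent, "clade")
            length = None
            branch_meta: list[MetaNode] = []
            if edge is not None:
                info = edge.start.payload
                length = info.length
                branch_meta = build_meta_tree(edge.content)
            if length is not None:
                clade.set("branch_length", repr(length))
            if node.start.label:
                ET.SubElement(clade, "name").text = node.start.label
            elements: list[ET.Element] = []
            properties: list[ET.Element] = []
            for meta_node in build_meta_tree(node.content):
                self._translate_annotation(meta_node, elements, "clade",
                                           strategy, log, node_id,
                                           properties=properties)
            for meta_node in branch_meta:
                self._translate_annotation(
                    meta_node, elements, "parent_branch", strategy, log,
                    node_id, properties=properties, branch=True)
            clade.extend(elements)
            clade.extend(properties)
            for child_edge in children.get(node_id, []):
                write_clade(child_edge.start.payload.target_id, clade,
                            child_edge)

        write_clade(roots[0], phylogeny, root_edge)
        for prop in properties:
            phylogeny.append(prop)

        if extra_edges:
            # assign id_source attributes to the clades involved
            clade_by_node: dict[str, ET.Element] = {}
            # replay the traversal to map nodes to clades in document order
            order: list[str] = []

            def collect(node_id: str) -> None:
                order.append(node_id)
                for child_edge in children.get(node_id, []):
                    collect(child_edge.start.payload.target_id)

            collect(roots[0])
            clades = phylogeny.iter("clade")
            for node_id, clade in zip(order, clades):
                clade_by_node[node_id] = clade
            for i, edge in enumerate(extra_edges):
                info = edge.start.payload
                for endpoint in (info.source_id, info.target_id):
                    if endpoint not in id_sources:
                        id_sources[endpoint] = f"is{len(id_sources) + 1}"
                        clade_by_node[endpoint].set("id_source",
                                                    id_sources[endpoint])
                rel_attrs = {"id_ref_0": id_sources[info.source_id],
                             "id_ref_1": id_sources[info.target_id],
                             "type": "network_connection"}
                for meta_node in build_meta_tree(edge.content):
                    if meta_node.kind == "literal" \
                            and meta_node.string_key == "crosslink_type":
                        rel_attrs["type"] = str(meta_node.value)
                if info.length is not None:
                    rel_attrs["distance"] = repr(info.length)
                phylogeny.append(ET.Element("clade_relation", rel_attrs))
        root.append(phylogeny)

    # -- annotation translation --------------------------------------------

    def _translate_annotation(self, node: MetaNode, elements: list,
                              scope: str, strategy: str, log: WarningLog,
                              subject_id: str,
                              properties: list | None = None,
                              branch: bool = False) -> None:
        if properties is None:
            properties = elements
        if node.kind == "comment":
            return
        if self._is_phyloxml_mapped(node):
            elements.append(self._render_mapped(node, log, subject_id))
            return
        if node.kind == "literal" and node.content_form == "xml" \
                and node.predicate is not None \
                and node.predicate.local_part == "customXml":
            from ..meta import xml_events_to_fragment
            elements.append(ET.fromstring(
                xml_events_to_fragment(node.value)))
            return
        if strategy == DROP_NON_REPRESENTABLE:
            log.warn("METADATA_DROPPED", subject_id,
                     f"{node.effective_key()!r} not representable in phyloXML")
            return
        # FLATTEN_LEAVES_TO_PROPERTIES
        literals = leaf_literals([node])
        if node.kind == "resource" or not literals:
            log.warn("HIERARCHY_FLATTENED", subject_id,
                     f"{node.effective_key()!r}: only leaf values written")
        for lit in literals:
            if lit.content_form == "xml":
                log.warn("METADATA_DROPPED", subject_id,
                         "nested XML value not representable as a property")
                continue
            attrs = {}
            if lit.predicate is not None:
                attrs["ref"] = self._ns.curie_for(lit.predicate)
            else:
                attrs["ref"] = lit.string_key or "annotation"
            datatype = lit.datatype
            if datatype is None and not isinstance(lit.value, str):
                from ..meta import format_literal
                _text, datatype = format_literal(lit.value)
            attrs["datatype"] = self._ns.curie_for(datatype) if datatype \
                else "xsd:string"
            attrs["applies_to"] = "parent_branch" if branch else (
                "phylogeny" if scope == "phylogeny" else "node")
            prop = ET.Element("property", attrs)
            from ..meta import format_literal as _fl
            text, _dt = _fl(lit.value) if not isinstance(lit.value, str) \
                else (lit.value, None)
            prop.text = text
            properties.append(prop)

    @staticmethod
    def _is_phyloxml_mapped(node: MetaNode) -> bool:
        if node.kind == "resource":
            return (node.rel is not None
                    and node.rel.namespace_uri == PHYLOXML_PREDICATE_NAMESPACE
                    and node.rel.local_part in _RESOURCE_CHILDREN
                    and all(child.kind == "literal"
                            and child.predicate is not None
                            and child.predicate.namespace_uri
                            == PHYLOXML_PREDICATE_NAMESPACE
                            for child in node.children))
        if node.kind == "literal":
            return (node.predicate is not None
                    and node.predicate.namespace_uri
                    == PHYLOXML_PREDICATE_NAMESPACE
                    and node.predicate.local_part == "confidence")
        return False

    def _render_mapped(self, node: MetaNode, log: WarningLog,
                       subject_id: str) -> ET.Element:
        if node.kind == "literal":  # confidence
            elem = ET.Element("confidence",
                              {"type": node.string_key or "unknown"})
            elem.text = str(node.value)
            return elem
        container = ET.Element(node.rel.local_part)
        allowed = _RESOURCE_CHILDREN[node.rel.local_part]
        ordered = sorted(
            node.children,
            key=lambda c: allowed.index(c.predicate.local_part.split("/")[-1])
            if c.predicate.local_part.split("/")[-1] in allowed else 99)
        for child in ordered:
            leaf = child.predicate.local_part.split("/")[-1]
            if leaf not in allowed:
                log.warn("METADATA_DROPPED", subject_id,
                         f"{child.predicate.curie()} has no phyloXML element")
                continue
            ET.SubElement(container, leaf).text = str(child.value)
        return container
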