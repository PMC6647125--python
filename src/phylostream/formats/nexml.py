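"""NeXML reading and writing.

NeXML is the lossless profile of this library: its RDFa ``meta`` elements
coincide with the internal metadata model, so documents — including
arbitrary-depth annotation trees, networks, custom token sets and element
sets — survive a write/read cycle with the full event stream intact.
Source IDs are reused verbatim as event IDs, and event IDs become element
IDs on writing.

Element mapping: ``otus``/``otu`` are OTU lists and OTUs, ``characters``
(with ``format``/``states``/``char`` declarations and either ``seq``- or
``cell``-style rows) are alignments with token set and character
definitions, ``trees`` groups hold ``tree`` and ``network`` elements with
``node``/``edge``/``rootedge`` children, and ``set`` elements become the
corresponding set events.  Every ``meta`` element maps 1:1 onto a literal
or resource metadata event.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from typing import IO, Iterator, Optional

from ..adapters import DocumentAdapter
from ..events import (EdgeInfo, Event, EventType, FormatError, Topology,
                      end, sole, start)
from ..meta import (LiteralContent, LiteralMetaInfo, Predicate,
                    ResourceMetaInfo, STRING_KEY_NAMESPACE, XSD_NAMESPACE,
                    format_literal, parse_literal, xml_events_to_fragment)
from ._base import EventReader, EventWriter, WriteResult

NEXML_NS = "http://www.nexml.org/2009"
XSI_NS = "http://www.w3.org/2001/XMLSchema-instance"
ET.register_namespace("xsi", XSI_NS)

#: reserved string key used to carry free-text comments through NeXML
_COMMENT_KEY = "comment"

_CLARK = re.compile(r"^\{([^}]*)\}(.*)$")


def _split_tag(tag: str) -> tuple[Optional[str], str]:
    m = _CLARK.match(tag)
    if m:
        return m.group(1), m.group(2)
    return None, tag


def _local(tag: str) -> str:
    return _split_tag(tag)[1]


class _NamespaceTable:
    """prefix <-> URI mapping collected from the document (and extended on
    writing).  CURIE rendering is reversible against this table."""

    def __init__(self) -> None:
        self.by_prefix: dict[str, str] = {"xsd": XSD_NAMESPACE}
        self.by_uri: dict[str, str] = {XSD_NAMESPACE: "xsd"}

    def declare(self, prefix: str, uri: str) -> None:
        self.by_prefix.setdefault(prefix, uri)
        self.by_uri.setdefault(uri, prefix)

    def resolve_curie(self, curie: str) -> Optional[Predicate]:
        prefix, sep, local = curie.partition(":")
        if not sep:
            return None
        uri = self.by_prefix.get(prefix)
        if uri is None:
            return None
        return Predicate(uri, local, prefix=prefix)

    def curie_for(self, predicate: Predicate) -> str:
        prefix = self.by_uri.get(predicate.namespace_uri)
        if prefix is None:
            prefix = predicate.prefix
            if prefix is None or prefix in self.by_prefix:
                i = 1
                while f"p{i}" in self.by_prefix:
                    i += 1
                prefix = f"p{i}"
            self.declare(prefix, predicate.namespace_uri)
        return f"{prefix}:{predicate.local_part}"


def _parse_with_namespaces(stream) -> tuple[ET.Element, _NamespaceTable]:
    text = stream.read()
    table = _NamespaceTable()
    root = None
    parser = ET.XMLPullParser(events=("start", "start-ns"))
    parser.feed(text)
    for event, payload in parser.read_events():
        if event == "start-ns":
            prefix, uri = payload
            table.declare(prefix or "", uri)
        elif root is None:
            root = payload
    parser.close()
    if root is None:
        raise FormatError("empty XML document", code="NEXML_SYNTAX")
    return root, table


# ---------------------------------------------------------------------------
# Reader
# ---------------------------------------------------------------------------

class NexmlReader(EventReader):
    format_id = "nexml"

    def events(self) -> Iterator[Event]:
        root, ns = _parse_with_namespaces(self.stream)
        ns_uri, local = _split_tag(root.tag)
        if local != "nexml" or (ns_uri not in (None, NEXML_NS)):
            raise FormatError("root element is not NeXML",
                              code="NEXML_SYNTAX")
        self._ns = ns
        self._seen: set[str] = set()
        # claim every source ID up front so generated IDs never collide
        for elem in root.iter():
            source = elem.get("id")
            if source:
                self.ids.claim(source)
        yield start(EventType.DOCUMENT, self._id_of(root, claim=True))
        yield from self._meta_events(root)
        otu_ids: set[str] = set()
        for child in root:
            kind = _local(child.tag)
            if kind == "otus":
                yield from self._read_otus(child, otu_ids)
            elif kind == "characters":
                yield from self._read_characters(child, otu_ids)
            elif kind == "trees":
                yield from self._read_trees(child, otu_ids)
        yield end(EventType.DOCUMENT)

    # -- helpers ------------------------------------------------------------

    def _id_of(self, elem: ET.Element, claim: bool = False) -> str:
        source = elem.get("id")
        if source:
            if source in self._seen:
                raise FormatError(f"duplicate id {source!r}",
                                  code="DUPLICATE_ID")
            self._seen.add(source)
            return self.ids.claim(source)
        return self.ids.new()

    def _is_meta(self, elem: ET.Element) -> bool:
        return _local(elem.tag) == "meta"

    def _meta_events(self, elem: ET.Element) -> Iterator[Event]:
        for child in elem:
            if self._is_meta(child):
                yield from self._read_meta(child)

    def _read_meta(self, elem: ET.Element) -> Iterator[Event]:
        xsi_type = elem.get(f"{{{XSI_NS}}}type", "")
        type_local = xsi_type.split(":")[-1]
        meta_id = self._id_of(elem)
        if type_local == "ResourceMeta" or elem.get("rel") is not None:
            rel = self._ns.resolve_curie(elem.get("rel", ""))
            if rel is None:
                raise FormatError(
                    f"unresolvable rel CURIE {elem.get('rel')!r}",
                    code="NEXML_SYNTAX")
            rel, string_key = self._unwrap_string_key(rel)
            yield start(EventType.RESOURCE_META, meta_id,
                        payload=ResourceMetaInfo(rel=rel,
                                                 href=elem.get("href"),
                                                 string_key=string_key))
            for child in elem:
                if self._is_meta(child):
                    yield from self._read_meta(child)
            yield end(EventType.RESOURCE_META)
            return
        predicate = self._ns.resolve_curie(elem.get("property", ""))
        string_key = None
        if predicate is not None:
            predicate, string_key = self._unwrap_string_key(predicate)
        if predicate is None and string_key == _COMMENT_KEY:
            # comments travel through NeXML as reserved-key literals
            yield sole(EventType.COMMENT, payload=elem.get("content", ""))
            return
        datatype = None
        if elem.get("datatype"):
            datatype = self._ns.resolve_curie(elem.get("datatype"))
        children = [c for c in elem if not self._is_meta(c)]
        if children:
            info = LiteralMetaInfo(predicate=predicate, string_key=string_key,
                                   datatype=datatype, content_form="xml")
            yield start(EventType.LITERAL_META, meta_id, payload=info)
            xml_events: list = []
            for child in children:
                xml_events.extend(self._foreign_xml_events(child))
            for i, xe in enumerate(xml_events):
                yield sole(EventType.LITERAL_META_CONTENT,
                           payload=LiteralContent(
                               xe, is_final=(i == len(xml_events) - 1),
                               content_form="xml"))
            yield end(EventType.LITERAL_META)
            return
        info = LiteralMetaInfo(predicate=predicate, string_key=string_key,
                               datatype=datatype, content_form="simple")
        yield start(EventType.LITERAL_META, meta_id, payload=info)
        text = elem.get("content")
        if text is None:
            text = (elem.text or "").strip() or None
        if text is not None:
            value = parse_literal(text, datatype)
            yield sole(EventType.LITERAL_META_CONTENT,
                       payload=LiteralContent(value))
        yield end(EventType.LITERAL_META)

    @staticmethod
    def _unwrap_string_key(predicate: Predicate
                           ) -> tuple[Optional[Predicate], Optional[str]]:
        # literals carrying only a free string key are serialized under a
        # reserved namespace; unwrap them back on reading
        if predicate.namespace_uri == STRING_KEY_NAMESPACE:
            return None, predicate.local_part
        return predicate, None

    def _foreign_xml_events(self, elem: ET.Element) -> list:
        events: list = []

        def clean_tag(tag: str) -> str:
            uri, local = _split_tag(tag)
            # the default document namespace is implementation detail
            return local if uri in (None, NEXML_NS) else tag

        def walk(e: ET.Element) -> None:
            events.append(("start", clean_tag(e.tag), dict(e.attrib)))
            if e.text and e.text.strip():
                events.append(("chars", e.text))
            for c in e:
                walk(c)
                if c.tail and c.tail.strip():
                    events.append(("chars", c.tail))
            events.append(("end", clean_tag(e.tag)))

        walk(elem)
        return events

    # -- sections -----------------------------------------------------------

    def _read_otus(self, elem: ET.Element, otu_ids: set[str]
                   ) -> Iterator[Event]:
        yield start(EventType.OTU_LIST, self._id_of(elem),
                    label=elem.get("label"))
        yield from self._meta_events(elem)
        sets = []
        for child in elem:
            kind = _local(child.tag)
            if kind == "otu":
                otu_id = self._id_of(child)
                otu_ids.add(otu_id)
                yield start(EventType.OTU, otu_id, label=child.get("label"))
                yield from self._meta_events(child)
                yield end(EventType.OTU)
            elif kind == "set":
                sets.append(child)
        for child in sets:
            members = (child.get("otu") or "").split()
            yield start(EventType.OTU_SET, self._id_of(child),
                        label=child.get("label"), payload=members)
            yield from self._meta_events(child)
            yield end(EventType.OTU_SET)
        yield end(EventType.OTU_LIST)

    def _read_characters(self, elem: ET.Element, otu_ids: set[str]
                         ) -> Iterator[Event]:
        yield start(EventType.ALIGNMENT, self._id_of(elem),
                    label=elem.get("label"), linked_id=elem.get("otus"))
        yield from self._meta_events(elem)

        fmt = next((c for c in elem if _local(c.tag) == "format"), None)
        states_symbols: dict[str, dict[str, str]] = {}  # set id -> state id -> symbol
        char_index: dict[str, int] = {}
        char_states: dict[int, Optional[str]] = {}
        char_elems: list[ET.Element] = []
        states_elems: list[ET.Element] = []
        if fmt is not None:
            for child in fmt:
                kind = _local(child.tag)
                if kind == "states":
                    states_elems.append(child)
                elif kind == "char":
                    char_elems.append(child)
            for child in states_elems:
                sid = child.get("id") or f"states{len(states_symbols)}"
                mapping: dict[str, str] = {}
                for state in child:
                    if _local(state.tag) in ("state", "polymorphic_state_set",
                                             "uncertain_state_set"):
                        symbol = state.get("symbol")
                        if symbol is not None:
                            mapping[state.get("id") or symbol] = symbol
                states_symbols[sid] = mapping
            for i, child in enumerate(char_elems):
                cid = child.get("id") or f"char{i}"
                char_index[cid] = i
                char_states[i] = child.get("states")

        # token set definitions: one per states element, covering the
        # columns whose char declarations reference it
        for child in states_elems:
            sid = child.get("id")
            columns = [i for i, s in char_states.items() if s == sid]
            payload = {
                "intervals": _columns_to_intervals(columns),
                "tokens": {state.get("symbol"): state.get("label")
                           or state.get("symbol")
                           for state in child
                           if _local(state.tag) == "state"
                           and state.get("symbol") is not None},
            }
            yield start(EventType.TOKEN_SET_DEFINITION, self._id_of(child),
                        label=child.get("label"), payload=payload)
            yield from self._meta_events(child)
            yield end(EventType.TOKEN_SET_DEFINITION)
        for i, child in enumerate(char_elems):
            has_meta = any(self._is_meta(c) for c in child)
            if child.get("label") is None and not has_meta:
                continue  # anonymous column declarations carry no information
            yield start(EventType.CHARACTER_DEFINITION, self._id_of(child),
                        label=child.get("label"), payload={"index": i})
            yield from self._meta_events(child)
            yield end(EventType.CHARACTER_DEFINITION)

        matrix = next((c for c in elem if _local(c.tag) == "matrix"), None)
        if matrix is not None:
            for row in matrix:
                if _local(row.tag) != "row":
                    continue
                otu = row.get("otu")
                if otu is not None and otu not in otu_ids:
                    raise FormatError(f"row references unknown otu {otu!r}",
                                      code="DANGLING_REFERENCE")
                yield start(EventType.SEQUENCE, self._id_of(row),
                            label=row.get("label"), linked_id=otu)
                yield from self._meta_events(row)
                tokens = self._row_tokens(row, char_index, states_symbols,
                                          char_states)
                if tokens:
                    yield sole(EventType.SEQUENCE_TOKENS, payload=tokens)
                yield end(EventType.SEQUENCE)

        for child in elem:
            if _local(child.tag) == "set":
                members = (child.get("char") or "").split()
                columns = [char_index[c] for c in members if c in char_index]
                yield start(EventType.CHARACTER_SET, self._id_of(child),
                            label=child.get("label"),
                            payload=_columns_to_intervals(columns))
                yield from self._meta_events(child)
                yield end(EventType.CHARACTER_SET)
        yield end(EventType.ALIGNMENT)

    def _row_tokens(self, row: ET.Element, char_index: dict[str, int],
                    states_symbols: dict[str, dict[str, str]],
                    char_states: dict[int, Optional[str]]) -> list[str]:
        cells = [c for c in row if _local(c.tag) == "cell"]
        if cells:
            by_column: dict[int, str] = {}
            for pos, cell in enumerate(cells):
                ref = cell.get("char")
                column = char_index.get(ref, pos) if ref else pos
                state = cell.get("state") or ""
                sid = char_states.get(column)
                symbols = states_symbols.get(sid, {}) if sid else {}
                by_column[column] = symbols.get(state, state)
            return [by_column[c] for c in sorted(by_column)]
        seq = next((c for c in row if _local(c.tag) == "seq"), None)
        if seq is None or seq.text is None:
            return []
        text = seq.text.strip()
        if not text:
            return []
        if any(ch.isspace() for ch in text):
            return text.split()
        return list(text)

    def _read_trees(self, elem: ET.Element, otu_ids: set[str]
                    ) -> Iterator[Event]:
        yield start(EventType.TREE_NETWORK_GROUP, self._id_of(elem),
                    label=elem.get("label"), linked_id=elem.get("otus"))
        yield from self._meta_events(elem)
        sets = []
        for child in elem:
            kind = _local(child.tag)
            if kind in ("tree", "network"):
                etype = (EventType.TREE if kind == "tree"
                         else EventType.NETWORK)
                yield start(etype, self._id_of(child),
                            label=child.get("label"))
                yield from self._meta_events(child)
                node_ids: set[str] = set()
                for sub in child:
                    sub_kind = _local(sub.tag)
                    if sub_kind == "node":
                        node_id = self._id_of(sub)
                        node_ids.add(node_id)
                        otu = sub.get("otu")
                        if otu is not None and otu not in otu_ids:
                            raise FormatError(
                                f"node references unknown otu {otu!r}",
                                code="DANGLING_REFERENCE")
                        payload = ({"root": True}
                                   if sub.get("root") == "true" else None)
                        yield start(EventType.NODE, node_id,
                                    label=sub.get("label"), linked_id=otu,
                                    payload=payload)
                        yield from self._meta_events(sub)
                        yield end(EventType.NODE)
                for sub in child:
                    sub_kind = _local(sub.tag)
                    if sub_kind in ("edge", "rootedge"):
                        etype2 = (EventType.EDGE if sub_kind == "edge"
                                  else EventType.ROOT_EDGE)
                        length = sub.get("length")
                        info = EdgeInfo(
                            source_id=sub.get("source"),
                            target_id=sub.get("target"),
                            length=float(length) if length is not None
                            else None)
                        yield start(etype2, self._id_of(sub),
                                    label=sub.get("label"), payload=info)
                        yield from self._meta_events(sub)
                        yield end(etype2)
                yield end(etype)
            elif kind == "set":
                sets.append(child)
        for child in sets:
            members = ((child.get("tree") or "").split()
                       + (child.get("network") or "").split())
            yield start(EventType.TREE_NETWORK_SET, self._id_of(child),
                        label=child.get("label"), payload=members)
            yield from self._meta_events(child)
            yield end(EventType.TREE_NETWORK_SET)
        yield end(EventType.TREE_NETWORK_GROUP)


def _columns_to_intervals(columns: list[int]) -> list[tuple[int, int]]:
    intervals: list[tuple[int, int]] = []
    for col in sorted(set(columns)):
        if intervals and intervals[-1][1] == col:
            intervals[-1] = (intervals[-1][0], col + 1)
        else:
            intervals.append((col, col + 1))
    return intervals


def _intervals_to_columns(intervals) -> list[int]:
    cols: list[int] = []
    for begin, stop in intervals or []:
        cols.extend(range(begin, stop))
    return cols


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------

class NexmlWriter(EventWriter):
    format_id = "nexml"

    def write(self, document: DocumentAdapter, stream: IO[str],
              **params) -> WriteResult:
        result = WriteResult()
        self._ns = _NamespaceTable()
        self._cell_style = params.get("cell_style", False)
        self._comment_counter = 0

        root = ET.Element("nexml", {"version": "0.9"})
        self._append_meta(root, document.document_metadata)
        for otu_list in document.otu_lists:
            self._write_otus(root, otu_list)
        for matrix in document.matrices:
            self._write_characters(root, matrix)
        for group in document.tree_network_groups:
            self._write_trees(root, group)

        root.set("xmlns", NEXML_NS)
        for uri, prefix in self._ns.by_uri.items():
            root.set(f"xmlns:{prefix}", uri)
        ET.indent(root)
        stream.write(ET.tostring(root, encoding="unicode") + "\n")
        return result

    # -- metadata -----------------------------------------------------------

    def _append_meta(self, parent: ET.Element, meta_events: list[Event]
                     ) -> None:
        # stack entries: [element, declared datatype, xml content buffer]
        stack: list[list] = [[parent, None, []]]
        for ev in meta_events:
            if ev.type is EventType.COMMENT:
                self._comment_counter += 1
                ET.SubElement(
                    stack[-1][0], "meta",
                    {"id": f"cmt{self._comment_counter}",
                     f"{{{XSI_NS}}}type": "nex:LiteralMeta",
                     "property": self._ns.curie_for(Predicate(
                         STRING_KEY_NAMESPACE, _COMMENT_KEY, prefix="pk")),
                     "content": ev.payload or ""})
                continue
            if ev.type is EventType.LITERAL_META \
                    and ev.topology is Topology.START:
                info: LiteralMetaInfo = ev.payload
                attrs = {"id": ev.id, f"{{{XSI_NS}}}type": "nex:LiteralMeta"}
                predicate = info.predicate
                if predicate is None:
                    predicate = Predicate(STRING_KEY_NAMESPACE,
                                          info.string_key, prefix="pk")
                attrs["property"] = self._ns.curie_for(predicate)
                if info.datatype is not None:
                    attrs["datatype"] = self._ns.curie_for(info.datatype)
                elem = ET.SubElement(stack[-1][0], "meta", attrs)
                stack.append([elem, info.datatype, []])
            elif ev.type is EventType.LITERAL_META_CONTENT:
                content: LiteralContent = ev.payload
                elem, declared, xml_buffer = stack[-1]
                if content.content_form == "xml":
                    xml_buffer.append(content.value)
                else:
                    text, inferred = format_literal(content.value)
                    if declared is None and not isinstance(content.value, str):
                        elem.set("datatype", self._ns.curie_for(inferred))
                    elem.set("content", text)
            elif ev.type is EventType.RESOURCE_META \
                    and ev.topology is Topology.START:
                rinfo: ResourceMetaInfo = ev.payload
                rel = rinfo.rel
                if rel is None:
                    rel = Predicate(STRING_KEY_NAMESPACE,
                                    rinfo.string_key or "resource",
                                    prefix="pk")
                attrs = {"id": ev.id, f"{{{XSI_NS}}}type": "nex:ResourceMeta",
                         "rel": self._ns.curie_for(rel)}
                if rinfo.href is not None:
                    attrs["href"] = rinfo.href
                elem = ET.SubElement(stack[-1][0], "meta", attrs)
                stack.append([elem, None, []])
            elif ev.topology is Topology.END and len(stack) > 1:
                elem, _declared, xml_buffer = stack.pop()
                if xml_buffer:
                    fragment = xml_events_to_fragment(xml_buffer)
                    elem.append(ET.fromstring(fragment))

    # -- sections -----------------------------------------------------------

    @staticmethod
    def _base_attrs(ev: Event) -> dict[str, str]:
        attrs = {"id": ev.id}
        if ev.label is not None:
            attrs["label"] = ev.label
        return attrs

    def _write_otus(self, root: ET.Element, otu_list) -> None:
        attrs = self._base_attrs(otu_list.start)
        elem = ET.SubElement(root, "otus", attrs)
        self._append_meta(elem, otu_list.metadata)
        for otu in otu_list.otus:
            otu_elem = ET.SubElement(elem, "otu", self._base_attrs(otu.start))
            self._append_meta(otu_elem, otu.content)
        for s in otu_list.otu_sets:
            set_elem = ET.SubElement(elem, "set", self._base_attrs(s.start))
            set_elem.set("otu", " ".join(s.start.payload or []))
            self._append_meta(set_elem, s.content)

    def _write_characters(self, root: ET.Element, matrix) -> None:
        attrs = self._base_attrs(matrix.start)
        if matrix.linked_otu_list:
            attrs["otus"] = matrix.linked_otu_list
        elem = ET.SubElement(root, "characters", attrs)
        elem.set(f"{{{XSI_NS}}}type",
                 "nex:StandardCells" if self._cell_style else "nex:StandardSeqs")
        self._append_meta(elem, matrix.metadata)
        fmt = ET.SubElement(elem, "format")
        nchar = matrix.column_count()

        labelled = {d.start.payload["index"]: d
                    for d in matrix.character_definitions
                    if isinstance(d.start.payload, dict)
                    and "index" in d.start.payload}
        column_states: dict[int, str] = {}
        for ts in matrix.token_sets:
            ts_attrs = self._base_attrs(ts.start)
            states_elem = ET.SubElement(fmt, "states", ts_attrs)
            self._append_meta(states_elem, ts.content)
            payload = ts.start.payload or {}
            tokens = payload.get("tokens") or {}
            for i, (symbol, token) in enumerate(tokens.items()):
                state_attrs = {"id": f"{ts.start.id}.s{i}", "symbol": symbol}
                if token != symbol:
                    state_attrs["label"] = token
                ET.SubElement(states_elem, "state", state_attrs)
            for col in _intervals_to_columns(payload.get("intervals")):
                column_states[col] = ts.start.id

        need_chars = bool(matrix.character_sets) or bool(labelled) \
            or bool(column_states) or self._cell_style
        self._char_ids: dict[int, str] = {}
        if need_chars:
            for i in range(nchar):
                if i in labelled:
                    definition = labelled[i]
                    char_attrs = self._base_attrs(definition.start)
                else:
                    char_attrs = {"id": f"{matrix.id}.c{i}"}
                if i in column_states:
                    char_attrs["states"] = column_states[i]
                self._char_ids[i] = char_attrs["id"]
                char_elem = ET.SubElement(fmt, "char", char_attrs)
                if i in labelled:
                    self._append_meta(char_elem, labelled[i].content)

        matrix_elem = ET.SubElement(elem, "matrix")
        for seq_id in matrix.sequence_ids():
            seq_start = matrix.get_sequence_start_event(seq_id)
            row_attrs = self._base_attrs(seq_start)
            if seq_start.linked_id:
                row_attrs["otu"] = seq_start.linked_id
            row = ET.SubElement(matrix_elem, "row", row_attrs)
            self._append_meta(row, matrix.sequence_metadata(seq_id))
            tokens = matrix.sequence_tokens(seq_id)
            if self._cell_style:
                for i, token in enumerate(tokens):
                    cell_attrs = {"state": token}
                    if i in self._char_ids:
                        cell_attrs["char"] = self._char_ids[i]
                    ET.SubElement(row, "cell", cell_attrs)
            elif tokens:
                seq_elem = ET.SubElement(row, "seq")
                joiner = "" if all(len(t) == 1 for t in tokens) else " "
                seq_elem.text = joiner.join(tokens)
        for s in matrix.character_sets:
            set_elem = ET.SubElement(elem, "set", self._base_attrs(s.start))
            columns = _intervals_to_columns(s.start.payload)
            set_elem.set("char", " ".join(self._char_ids[c] for c in columns
                                          if c in self._char_ids))
            self._append_meta(set_elem, s.content)

    def _write_trees(self, root: ET.Element, group) -> None:
        attrs = self._base_attrs(group.start)
        if group.linked_otu_list:
            attrs["otus"] = group.linked_otu_list
        elem = ET.SubElement(root, "trees", attrs)
        self._append_meta(elem, group.metadata)
        for member in group.members:
            kind = "network" if member.is_network else "tree"
            member_elem = ET.SubElement(elem, kind,
                                        self._base_attrs(member.start))
            member_elem.set(f"{{{XSI_NS}}}type",
                            "nex:FloatNetwork" if member.is_network
                            else "nex:FloatTree")
            self._append_meta(member_elem, member.metadata)
            for node_id in member.node_ids():
                node = member.nodes[node_id]
                node_attrs = self._base_attrs(node.start)
                if node.start.linked_id:
                    node_attrs["otu"] = node.start.linked_id
                if isinstance(node.start.payload, dict) \
                        and node.start.payload.get("root"):
                    node_attrs["root"] = "true"
                node_elem = ET.SubElement(member_elem, "node", node_attrs)
                self._append_meta(node_elem, node.content)
            for edge in member.edges:
                info: EdgeInfo = edge.start.payload
                tag = "rootedge" if edge.start.type is EventType.ROOT_EDGE \
                    else "edge"
                edge_attrs = self._base_attrs(edge.start)
                if info.source_id is not None:
                    edge_attrs["source"] = info.source_id
                edge_attrs["target"] = info.target_id
                if info.length is not None:
                    edge_attrs["length"] = repr(info.length)
                edge_elem = ET.SubElement(member_elem, tag, edge_attrs)
                self._append_meta(edge_elem, edge.content)
        tree_ids = {m.id for m in group.members if not m.is_network}
        for s in group.sets:
            set_elem = ET.SubElement(elem, "set", self._base_attrs(s.start))
            members = s.start.payload or []
            trees_ref = [m for m in members if m in tree_ids]
            networks_ref = [m for m in members if m not in tree_ids]
            if trees_ref:
                set_elem.set("tree", " ".join(trees_ref))
            if networks_ref:
                set_elem.set("network", " ".join(networks_ref))
            self._append_meta(set_elem, s.content)
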