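"""Newick tokenizing, parsing and writing.

The same engine serves standalone Newick files (one or more
semicolon-separated trees) and the TREE commands of NEXUS files.  Bracket
comments that carry actual metadata ("hot comments") are decoded: the NHX
extension (``[&&NHX:S=human:B=95]``, keys mapped to the internal phyloXML
predicates) and the BEAST/MrBayes key-value style
(``[&height=1.0,range={0.5,1.5}]``, free string keys with typed scalar or
array values).  A comment before the ``:`` of a branch annotates the node,
one after it the branch.  Repeated hybrid-tagged nodes (``#H1``) written in
Extended Newick are merged into single network nodes by
:func:`resolve_enewick`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterator, Optional

from ..adapters import (DocumentAdapter, TreeOrNetworkAdapter, WarningLog)
from ..events import (EdgeInfo, Event, EventType, FormatError, IdSource,
                      Topology, end, sole, start)
from ..meta import (MetaNode, PHYLOXML_PREDICATE_NAMESPACE, Predicate,
                    build_meta_tree, emit_meta_tree, format_array_literal,
                    leaf_literals, parse_scalar, simple_literal)
from ._base import EventReader, EventWriter, WriteResult

# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

STRUCTURAL = "(),:;"
_UNQUOTED_FORBIDDEN = set("()[]:;,'") | set(" \t\r\n")


@dataclass
class Token:
    kind: str          # "punct" | "name" | "comment"
    value: str
    offset: int
    quoted: bool = False


def tokenize_newick(text: str) -> list[Token]:
    """Lex a Newick string into punctuation, name/number and comment tokens.

    Quoted names use ``''`` as the escape for a single quote; underscores in
    unquoted names denote spaces.  Comments keep their bracket interior and
    remain attached to the structural position where they occurred.
    """
    tokens: list[Token] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c in STRUCTURAL:
            tokens.append(Token("punct", c, i))
            i += 1
        elif c == "[":
            depth, j = 1, i + 1
            while j < n and depth:
                if text[j] == "[":
                    depth += 1
                elif text[j] == "]":
                    depth -= 1
                j += 1
            if depth:
                raise FormatError("unterminated comment", column=i,
                                  code="NEWICK_SYNTAX")
            tokens.append(Token("comment", text[i + 1:j - 1], i))
            i = j
        elif c == "'":
            j = i + 1
            parts: list[str] = []
            while True:
                if j >= n:
                    raise FormatError("unterminated quoted name", column=i,
                                      code="NEWICK_SYNTAX")
                if text[j] == "'":
                    if j + 1 < n and text[j + 1] == "'":
                        parts.append("'")
                        j += 2
                        continue
                    break
                parts.append(text[j])
                j += 1
            tokens.append(Token("name", "".join(parts), i, quoted=True))
            i = j + 1
        else:
            j = i
            while j < n and text[j] not in _UNQUOTED_FORBIDDEN:
                j += 1
            tokens.append(Token("name", text[i:j].replace("_", " "), i))
            i = j
    return tokens


# ---------------------------------------------------------------------------
# Hot comments
# ---------------------------------------------------------------------------

@dataclass
class HotComment:
    kind: str                                  # "NHX" | "KEY_VALUE" | "PLAIN"
    entries: list[tuple[str, object]] = field(default_factory=list)
    attachment: str = "node"                   # "node" | "branch"
    text: str = ""


#: NHX tag -> internal phyloXML predicate local path.
NHX_PREDICATES = {
    "S": "taxonomy/scientific_name",
    "T": "taxonomy/id",
    "B": "confidence",
    "AC": "sequence/accession",
    "GN": "sequence/name",
    "D": "events/duplications",
    "E": "annotation/ref",
    "O": "node_id",
}
_NHX_BY_PATH = {v: k for k, v in NHX_PREDICATES.items()}


def phyloxml_predicate(path: str) -> Predicate:
    return Predicate(PHYLOXML_PREDICATE_NAMESPACE, path, prefix="px")


def parse_hot_comment(text: str, after_colon: bool = False) -> HotComment:
    """Classify a bracket-comment interior.

    Unparseable interiors degrade to PLAIN (a free-text comment event),
    never to an error.
    """
    attachment = "branch" if after_colon else "node"
    if text.startswith("&&NHX"):
        entries: list[tuple[str, object]] = []
        for part in text[5:].split(":"):
            if not part:
                continue
            key, sep, value = part.partition("=")
            if not sep:
                return HotComment("PLAIN", text=text, attachment=attachment)
            entries.append((key, parse_scalar(value)))
        return HotComment("NHX", entries, attachment, text)
    if text.startswith("&"):
        try:
            entries = _parse_key_values(text[1:])
        except ValueError:
            return HotComment("PLAIN", text=text, attachment=attachment)
        return HotComment("KEY_VALUE", entries, attachment, text)
    return HotComment("PLAIN", text=text, attachment=attachment)


def _parse_key_values(body: str) -> list[tuple[str, object]]:
    entries: list[tuple[str, object]] = []
    i, n = 0, len(body)
    while i < n:
        j = body.find("=", i)
        if j < 0:
            key = body[i:].strip()
            if not key:
                break
            raise ValueError(f"entry without value: {key!r}")
        key = body[i:j].strip()
        if not key:
            raise ValueError("empty key")
        i = j + 1
        if i < n and body[i] == "{":
            k = body.find("}", i)
            if k < 0:
                raise ValueError("unterminated array value")
            value_text = body[i:k + 1]
            i = k + 1
        elif i < n and body[i] == '"':
            k = body.find('"', i + 1)
            if k < 0:
                raise ValueError("unterminated quoted value")
            value_text = body[i:k + 1]
            i = k + 1
        else:
            k = body.find(",", i)
            if k < 0:
                k = n
            value_text = body[i:k]
            i = k
        if i < n and body[i] == ",":
            i += 1
        if value_text.startswith("{"):
            inner = value_text[1:-1]
            value: object = [parse_scalar(p) for p in inner.split(",")] \
                if inner else []
        else:
            value = parse_scalar(value_text)
        entries.append((key, value))
    return entries


def hot_comment_meta(hc: HotComment) -> list[MetaNode]:
    """Translate a hot comment into literal metadata nodes."""
    nodes: list[MetaNode] = []
    for key, value in hc.entries:
        if hc.kind == "NHX" and key in NHX_PREDICATES:
            nodes.append(MetaNode(kind="literal",
                                  predicate=phyloxml_predicate(
                                      NHX_PREDICATES[key]),
                                  value=value))
        else:
            nodes.append(MetaNode(kind="literal", string_key=key, value=value))
    return nodes


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

@dataclass
class _PNode:
    label: Optional[str] = None
    quoted_label: bool = False
    length: Optional[float] = None
    node_comments: list[str] = field(default_factory=list)
    branch_comments: list[str] = field(default_factory=list)
    children: list["_PNode"] = field(default_factory=list)


def _parse_tree_tokens(tokens: list[Token], pos: int = 0) -> tuple[_PNode, int]:
    """Parse tokens of one tree (up to and including ';')."""

    def parse_element(i: int) -> tuple[_PNode, int]:
        node = _PNode()
        if i < len(tokens) and tokens[i].kind == "punct" and tokens[i].value == "(":
            i += 1
            while True:
                child, i = parse_element(i)
                node.children.append(child)
                if i >= len(tokens):
                    raise FormatError("unbalanced parentheses",
                                      code="NEWICK_SYNTAX")
                t = tokens[i]
                if t.kind == "punct" and t.value == ",":
                    i += 1
                    continue
                if t.kind == "punct" and t.value == ")":
                    i += 1
                    break
                raise FormatError(f"unexpected token {t.value!r}",
                                  column=t.offset, code="NEWICK_SYNTAX")
        # label, node comments, branch length, branch comments
        while i < len(tokens):
            t = tokens[i]
            if t.kind == "name" and node.label is None and node.length is None:
                node.label = t.value
                node.quoted_label = t.quoted
                i += 1
            elif t.kind == "comment":
                node.node_comments.append(t.value)
                i += 1
            elif t.kind == "punct" and t.value == ":":
                i += 1
                # comments may sit between ':' and the number
                while i < len(tokens) and tokens[i].kind == "comment":
                    node.branch_comments.append(tokens[i].value)
                    i += 1
                if i >= len(tokens) or tokens[i].kind != "name":
                    raise FormatError("':' without branch length",
                                      code="NEWICK_SYNTAX")
                if node.length is not None:
                    raise FormatError("two lengths on one branch",
                                      column=tokens[i].offset,
                                      code="NEWICK_SYNTAX")
                try:
                    node.length = float(tokens[i].value)
                except ValueError as exc:
                    raise FormatError(
                        f"invalid branch length {tokens[i].value!r}",
                        column=tokens[i].offset,
                        code="NEWICK_SYNTAX") from exc
                i += 1
                while i < len(tokens) and tokens[i].kind == "comment":
                    node.branch_comments.append(tokens[i].value)
                    i += 1
            else:
                break
        return node, i

    root, i = parse_element(pos)
    if i >= len(tokens) or tokens[i].kind != "punct" or tokens[i].value != ";":
        t = tokens[i] if i < len(tokens) else None
        raise FormatError(
            f"expected ';' after tree, found {t.value!r}" if t else
            "expected ';' after tree", code="NEWICK_SYNTAX",
            column=t.offset if t else None)
    return root, i + 1


def _comment_meta(comments: list[str], after_colon: bool) -> list[MetaNode]:
    nodes: list[MetaNode] = []
    for text in comments:
        hc = parse_hot_comment(text, after_colon=after_colon)
        if hc.kind == "PLAIN":
            nodes.append(MetaNode(kind="comment", comment=hc.text))
        else:
            nodes.extend(hot_comment_meta(hc))
    return nodes


def parse_newick(tokens: list[Token], ids: IdSource,
                 tree_id: str | None = None,
                 label: str | None = None,
                 extra_tree_meta: list[MetaNode] | None = None,
                 resolve_label=None) -> list[Event]:
    """Emit the TREE event subsequence for one tokenized Newick string.

    Nodes appear in post-order (children before parents); each edge event
    follows both its endpoint node events and carries the branch length.  A
    length on the outermost element becomes a root edge.  ``resolve_label``
    optionally maps a node label to ``(label, otu_id)`` (NEXUS taxon
    resolution).
    """
    root, next_pos = _parse_tree_tokens(tokens)
    if next_pos < len(tokens):
        raise FormatError("trailing tokens after tree",
                          column=tokens[next_pos].offset,
                          code="NEWICK_SYNTAX")
    return _emit_tree(root, ids, tree_id, label, extra_tree_meta,
                      resolve_label)


def _emit_tree(root: _PNode, ids: IdSource, tree_id: str | None,
               label: str | None, extra_tree_meta, resolve_label) -> list[Event]:
    events: list[Event] = [start(EventType.TREE, tree_id or ids.new(),
                                 label=label)]
    if extra_tree_meta:
        events.extend(emit_meta_tree(extra_tree_meta, ids))
    edges: list[Event] = []

    def emit_node(pnode: _PNode, is_leaf_context: bool) -> str:
        child_ids = [emit_node(c, True) for c in pnode.children]
        node_id = ids.new()
        node_label = pnode.label
        linked = None
        if resolve_label is not None and node_label is not None:
            resolved = resolve_label(node_label, bool(pnode.children))
            if resolved is not None:
                node_label, linked = resolved
        events.append(start(EventType.NODE, node_id, label=node_label,
                            linked_id=linked))
        events.extend(emit_meta_tree(
            _comment_meta(pnode.node_comments, False), ids))
        events.append(end(EventType.NODE))
        for child, child_id in zip(pnode.children, child_ids):
            edge = start(EventType.EDGE, ids.new(),
                         payload=EdgeInfo(node_id, child_id, child.length))
            events.append(edge)
            events.extend(emit_meta_tree(
                _comment_meta(child.branch_comments, True), ids))
            events.append(end(EventType.EDGE))
        return node_id

    root_id = emit_node(root, False)
    if root.length is not None or root.branch_comments:
        events.append(start(EventType.ROOT_EDGE, ids.new(),
                            payload=EdgeInfo(None, root_id, root.length)))
        events.extend(emit_meta_tree(
            _comment_meta(root.branch_comments, True), ids))
        events.append(end(EventType.ROOT_EDGE))
    events.append(end(EventType.TREE))
    return events


# ---------------------------------------------------------------------------
# Extended Newick network resolution
# ---------------------------------------------------------------------------

_HYBRID = re.compile(r"^(.*?)#([A-Za-z]*)(\d+)$")

_CROSSLINK_TYPES = {"H": "H", "LGT": "LGT", "R": "R", "": "H"}


def resolve_enewick(tree_events: list[Event],
                    warnings: WarningLog | None = None) -> list[Event]:
    """Merge hybrid-tagged nodes of one TREE event subsequence.

    All nodes whose label carries one hybrid tag (``#H1``, ``#LGT2``...)
    are identified; incoming edges are re-targeted to the surviving node.
    The result is emitted as a NETWORK when at least one merge occurred and
    is returned unchanged otherwise.  The tag's type letter is recorded as
    literal metadata (crosslink type) on the merged node.
    """
    # collect nodes and their tags
    tag_nodes: dict[str, list[str]] = {}
    node_events: dict[str, list[Event]] = {}
    order: list[Event] = []
    current: list[Event] | None = None
    for ev in tree_events:
        order.append(ev)
        if ev.type is EventType.NODE and ev.topology is Topology.START:
            current = [ev]
            node_events[ev.id] = current
            if ev.label:
                m = _HYBRID.match(ev.label)
                if m:
                    tag = "#" + m.group(2) + m.group(3)
                    tag_nodes.setdefault(tag, []).append(ev.id)
        elif current is not None:
            current.append(ev)
            if ev.type is EventType.NODE and ev.topology is Topology.END:
                current = None

    merges = {tag: ids_ for tag, ids_ in tag_nodes.items() if len(ids_) > 1}
    for tag, ids_ in tag_nodes.items():
        if len(ids_) == 1 and warnings is not None:
            warnings.warn("DANGLING_HYBRID", ids_[0],
                          f"hybrid tag {tag!r} occurs only once")
    if not merges:
        return tree_events

    # survivor: the first occurrence of each tag
    replacement: dict[str, str] = {}
    tag_of_survivor: dict[str, str] = {}
    for tag, ids_ in merges.items():
        survivor = ids_[0]
        tag_of_survivor[survivor] = tag
        for other in ids_[1:]:
            replacement[other] = survivor
    for tag, ids_ in tag_nodes.items():
        if len(ids_) == 1:
            tag_of_survivor[ids_[0]] = tag

    ids = IdSource("n")
    out: list[Event] = []
    skip_depth = 0
    for ev in tree_events:
        if skip_depth:
            if ev.topology is Topology.START:
                skip_depth += 1
            elif ev.topology is Topology.END:
                skip_depth -= 1
            continue
        if ev.type is EventType.TREE:
            out.append(Event(EventType.NETWORK, ev.topology, id=ev.id,
                             label=ev.label, linked_id=ev.linked_id,
                             payload=ev.payload))
            continue
        if ev.type is EventType.NODE and ev.topology is Topology.START:
            if ev.id in replacement:
                skip_depth = 1  # drop the duplicate node's whole subtree
                continue
            label = ev.label
            extra_meta: list[Event] = []
            if ev.id in tag_of_survivor and label:
                m = _HYBRID.match(label)
                if m:
                    label = m.group(1) or None
                    letter = m.group(2).upper()
                    crosslink = _CROSSLINK_TYPES.get(letter, letter or "H")
                    extra_meta = simple_literal(
                        string_key="crosslink_type",
                        value=crosslink, ids=ids)
            out.append(Event(EventType.NODE, Topology.START, id=ev.id,
                             label=label, linked_id=ev.linked_id))
            out.extend(extra_meta)
            continue
        if ev.type in (EventType.EDGE, EventType.ROOT_EDGE) \
                and ev.topology is Topology.START and isinstance(ev.payload,
                                                                 EdgeInfo):
            info = ev.payload
            src = replacement.get(info.source_id, info.source_id) \
                if info.source_id else info.source_id
            tgt = replacement.get(info.target_id, info.target_id)
            out.append(Event(ev.type, Topology.START, id=ev.id,
                             label=ev.label,
                             payload=EdgeInfo(src, tgt, info.length)))
            continue
        out.append(ev)
    return out


# ---------------------------------------------------------------------------
# Reader and writer
# ---------------------------------------------------------------------------

class NewickReader(EventReader):
    format_id = "newick"

    def events(self) -> Iterator[Event]:
        text = self.stream.read()
        yield start(EventType.DOCUMENT, self.ids.new())
        tokens = tokenize_newick(text)
        if tokens:
            yield start(EventType.TREE_NETWORK_GROUP, self.ids.new())
            pos = 0
            index = 0
            while pos < len(tokens):
                # leading comments between trees become group-level comments
                while pos < len(tokens) and tokens[pos].kind == "comment":
                    yield sole(EventType.COMMENT, payload=tokens[pos].value)
                    pos += 1
                if pos >= len(tokens):
                    break
                root, pos = _parse_tree_tokens(tokens, pos)
                index += 1
                tree_events = _emit_tree(root, self.ids, None,
                                         f"tree{index}", None, None)
                yield from resolve_enewick(tree_events, self.warnings)
            yield end(EventType.TREE_NETWORK_GROUP)
        yield end(EventType.DOCUMENT)


def quote_label(label: str) -> str:
    """Quote a label when it contains structural characters; spaces render
    as underscores when that is unambiguous."""
    needs_quote = bool(set(label) & (_UNQUOTED_FORBIDDEN - {" "})) \
        or "_" in label or label == ""
    if not needs_quote:
        return label.replace(" ", "_")
    return "'" + label.replace("'", "''") + "'"


def format_hot_value(value: object) -> str:
    if isinstance(value, (list, tuple)):
        return format_array_literal(value)
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, str) and ("," in value or "=" in value
                                   or "{" in value or "}" in value
                                   or " " in value):
        return '"' + value + '"'
    return str(value)


def serialize_tree_newick(tree: TreeOrNetworkAdapter,
                          log: WarningLog,
                          metadata_style: str = "KEY_VALUE",
                          label_for_node=None,
                          ids: IdSource | None = None) -> str:
    """Serialize one tree adapter as a Newick string (without trailing
    newline, with ';').

    Hierarchical metadata is flattened: only the leaf literals of each
    annotation tree are written as hot comments (keyed by their string key
    or the derived CURIE local part); dropped structure is warned about.
    Networks cannot be expressed here and must go through the eNewick door
    of the NEXUS module or be declined by the caller.
    """
    children: dict[str, list[tuple[str, Optional[float], list[Event]]]] = {}
    incoming: set[str] = set()
    root_edge = None
    for edge in tree.edges:
        info: EdgeInfo = edge.start.payload
        if edge.start.type is EventType.ROOT_EDGE or info.source_id is None:
            root_edge = edge
            continue
        children.setdefault(info.source_id, []).append(
            (info.target_id, info.length, edge.content))
        incoming.add(info.target_id)
    roots = [n for n in tree.node_ids() if n not in incoming]
    if not roots:
        raise FormatError("tree has no root node", code="NEWICK_WRITE")
    root = roots[0]

    def meta_comment(meta_events: list[Event], subject: str) -> str:
        nodes = build_meta_tree(meta_events)
        literals = leaf_literals(nodes)
        for lit in list(literals):
            if lit.content_form == "xml":
                log.warn("METADATA_DROPPED", subject,
                         "XML metadata content has no hot-comment form")
                literals.remove(lit)
        flattened = any(n.kind == "resource" or
                        (n.kind == "literal" and n not in literals)
                        for n in nodes)
        if flattened or any(n.kind == "resource" for n in nodes):
            log.warn("HIERARCHY_FLATTENED", subject,
                     "only lowest-level metadata written as hot comments")
        if metadata_style == "NONE":
            for lit in literals:
                log.warn("METADATA_DROPPED", subject,
                         f"{lit.effective_key()!r} dropped (style NONE)")
            return ""
        if not literals:
            return ""
        if metadata_style == "NHX":
            parts = []
            for lit in literals:
                key = None
                if lit.predicate is not None and \
                        lit.predicate.namespace_uri == PHYLOXML_PREDICATE_NAMESPACE:
                    key = _NHX_BY_PATH.get(lit.predicate.local_part)
                parts.append(f"{key or lit.effective_key()}="
                             f"{format_hot_value(lit.value)}")
            return "[&&NHX:" + ":".join(parts) + "]"
        parts = [f"{lit.effective_key()}={format_hot_value(lit.value)}"
                 for lit in literals]
        return "[&" + ",".join(parts) + "]"

    def serialize(node_id: str) -> str:
        node = tree.nodes[node_id]
        kids = children.get(node_id, [])
        inner = ""
        if kids:
            inner = "(" + ",".join(
                serialize(child_id) + _branch_suffix(length, content, child_id)
                for child_id, length, content in kids) + ")"
        label = node.start.label
        if label_for_node is not None:
            label = label_for_node(node)
        text = inner + (quote_label(label) if label else "")
        text += meta_comment(node.content, node_id)
        return text

    def _branch_suffix(length: Optional[float], content: list[Event],
                       target: str) -> str:
        comment = meta_comment(content, target)
        if length is None:
            # without a length there is no branch position in the string
            if comment:
                log.warn("METADATA_DROPPED", target,
                         "branch metadata on a length-less branch")
            return ""
        return ":" + comment + repr(length)

    text = serialize(root)
    if root_edge is not None:
        info = root_edge.start.payload
        comment = meta_comment(root_edge.content, root)
        if info.length is not None:
            text += ":" + comment + repr(info.length)
        elif comment:
            text += ":" + comment + "0.0"
    return text + ";"


class NewickWriter(EventWriter):
    format_id = "newick"

    def write(self, document: DocumentAdapter, stream: IO[str],
              **params) -> WriteResult:
        style = params.get("metadata_style", "KEY_VALUE")
        result = WriteResult()
        log = result.warnings
        from .fasta import _meta_subtrees, _warn_dropped
        for meta in _meta_subtrees(document.document_metadata):
            _warn_dropped(log, meta, None)
        for matrix in document.matrices:
            log.warn("CONTENT_DROPPED", matrix.id,
                     "matrices cannot be written to Newick files")
        for otu_list in document.otu_lists:
            for meta in _meta_subtrees(otu_list.metadata):
                _warn_dropped(log, meta, otu_list.id)
        for group in document.tree_network_groups:
            for meta in _meta_subtrees(group.metadata):
                _warn_dropped(log, meta, group.id)
            for member in group.members:
                if member.is_network:
                    text = serialize_network_enewick(member, log, style)
                else:
                    for meta in _meta_subtrees(member.metadata):
                        _warn_dropped(log, meta, member.id)
                    text = serialize_tree_newick(member, log, style)
                stream.write(text + "\n")
        return result


def serialize_network_enewick(network: TreeOrNetworkAdapter,
                              log: WarningLog,
                              metadata_style: str = "KEY_VALUE") -> str:
    """Serialize a network adapter as an Extended Newick string.

    Nodes with several parents are split into one primary occurrence (kept
    with its children) and hybrid-tagged leaf duplicates, inverting the
    merge performed on reading.
    """
    from ..meta import build_meta_tree as _bmt
    in_edges: dict[str, list] = {}
    children: dict[str, list[tuple[str, Optional[float], list[Event]]]] = {}
    for edge in network.edges:
        info: EdgeInfo = edge.start.payload
        if info.source_id is None:
            continue
        in_edges.setdefault(info.target_id, []).append(edge)
        children.setdefault(info.source_id, []).append(
            (info.target_id, info.length, edge.content))
    hybrid_ids = {n for n, es in in_edges.items() if len(es) > 1}
    tags: dict[str, str] = {}
    counter = 1
    for node_id in network.node_ids():
        if node_id in hybrid_ids:
            # reuse a recorded crosslink type when present
            letter = "H"
            for node in [network.nodes[node_id]]:
                for mn in _bmt(node.content):
                    if mn.kind == "literal" and \
                            (mn.string_key == "crosslink_type"
                             or (mn.predicate is not None
                                 and mn.predicate.local_part == "crosslinkType")):
                        letter = str(mn.value)
            tags[node_id] = f"#{letter}{counter}"
            counter += 1

    roots = [n for n in network.node_ids() if n not in in_edges]
    if not roots:
        raise FormatError("network has no root node", code="NEWICK_WRITE")
    visited_hybrids: set[str] = set()

    def meta_comment(meta_events: list[Event], subject: str) -> str:
        nodes = _bmt(meta_events)
        literals = [n for n in leaf_literals(nodes)
                    if n.string_key != "crosslink_type"
                    and n.content_form != "xml"]
        if metadata_style == "NONE" or not literals:
            return ""
        parts = [f"{lit.effective_key()}={format_hot_value(lit.value)}"
                 for lit in literals]
        return "[&" + ",".join(parts) + "]"

    def serialize(node_id: str) -> str:
        node = network.nodes[node_id]
        label = node.start.label or ""
        if node_id in tags:
            # the tag is part of the (possibly quoted) label token
            full = label + tags[node_id]
            if node_id in visited_hybrids:
                return quote_label(full)
            visited_hybrids.add(node_id)
            label_text = quote_label(full)
        else:
            label_text = quote_label(label) if label else ""
        kids = children.get(node_id, [])
        inner = ""
        if kids:
            inner = "(" + ",".join(
                serialize(cid)
                + meta_comment([], cid)
                + ("" if length is None else ":" + repr(length))
                for cid, length, _content in kids) + ")"
        return inner + label_text + meta_comment(node.content, node_id)

    return serialize(roots[0]) + ";"
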