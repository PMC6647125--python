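"""Generalized RDF-style metadata model.

Annotations on any document element are modelled as nested literal and
resource metadata events.  A literal meta carries a typed value; a
resource meta links a URI and/or groups nested annotations.  Both can be
identified by an RDF predicate (a CURIE with a namespace) and/or by a free
string key — the dual identification lets the same annotation flow into
NeXML (predicates), BEAST-style hot comments (string keys) or phyloXML
property tags (either).  Formats without namespace support fall back to
the local part of the predicate CURIE via :func:`derive_string_key`.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Optional

from .events import (Event, EventType, FormatError, IdSource, Topology,
                     end, sole, start)

XSD_NAMESPACE = "http://www.w3.org/2001/XMLSchema#"
#: Namespace of the internal predicates identifying phyloXML's fixed elements.
PHYLOXML_PREDICATE_NAMESPACE = "https://phylostream.example/predicates/phyloxml/"
#: Namespace used when a string key must be rendered as a predicate (NeXML).
STRING_KEY_NAMESPACE = "https://phylostream.example/predicates/stringKeys/"
#: Namespace for reserved internal predicates (rootedness, crosslink types...).
INTERNAL_NAMESPACE = "https://phylostream.example/predicates/internal/"
#: Namespace for non-XSD value datatypes (arrays).
DATATYPE_NAMESPACE = "https://phylostream.example/datatypes/"


@dataclass(frozen=True)
class Predicate:
    """An RDF predicate: namespace URI plus local part.

    Rendering as a CURIE ``prefix:local_part`` is reversible given a
    namespace table mapping prefixes to namespace URIs.
    """

    namespace_uri: str
    local_part: str
    prefix: Optional[str] = None

    def curie(self) -> str:
        return f"{self.prefix or 'p'}:{self.local_part}"

    @property
    def uri(self) -> str:
        return self.namespace_uri + self.local_part


def xsd(local_part: str) -> Predicate:
    return Predicate(XSD_NAMESPACE, local_part, prefix="xsd")


ROOTED_PREDICATE = Predicate(INTERNAL_NAMESPACE, "isRooted", prefix="pint")
CROSSLINK_PREDICATE = Predicate(INTERNAL_NAMESPACE, "crosslinkType", prefix="pint")


@dataclass
class LiteralMetaInfo:
    """Payload of a LITERAL_META start event."""

    predicate: Optional[Predicate] = None
    string_key: Optional[str] = None
    datatype: Optional[Predicate] = None
    content_form: str = "simple"  # "simple" or "xml"

    def __post_init__(self) -> None:
        if self.predicate is None and self.string_key is None:
            raise ValueError("literal meta needs a predicate or a string key")


@dataclass
class LiteralContent:
    """Payload of a LITERAL_META_CONTENT event.

    ``value`` is a typed scalar, an array of scalars, or (for XML content)
    one generic XML event tuple.  Large simple values may be split over
    several content events; ``is_final`` marks the last one.
    """

    value: Any
    is_final: bool = True
    content_form: str = "simple"


@dataclass
class ResourceMetaInfo:
    """Payload of a RESOURCE_META start event."""

    rel: Predicate
    href: Optional[str] = None
    string_key: Optional[str] = None


def derive_string_key(predicate: Predicate) -> str:
    """String identifier used when a format needs one and none was given:
    the local part of the predicate CURIE."""
    return predicate.local_part


# ---------------------------------------------------------------------------
# Literal value translation (text <-> typed values)
# ---------------------------------------------------------------------------

_TRUE = {"true", "1"}
_FALSE = {"false", "0"}


def _parse_boolean(text: str) -> bool:
    low = text.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(text)


class LiteralValueTranslators:
    """Registry of datatype translators, extensible with custom types.

    Default coverage: the XSD types string, boolean, int, integer, long,
    float, double, decimal and anyURI, plus internal array datatypes for
    BEAST-style ``{a,b,c}`` values.
    """

    def __init__(self) -> None:
        self._parsers: dict[str, Callable[[str], Any]] = {}
        self._formatters: list[tuple[type, Callable[[Any], tuple[str, Predicate]]]] = []
        self._register_defaults()

    def register_parser(self, datatype: Predicate,
                        fn: Callable[[str], Any]) -> None:
        self._parsers[datatype.uri] = fn

    def register_formatter(self, pytype: type,
                           fn: Callable[[Any], tuple[str, Predicate]]) -> None:
        self._formatters.insert(0, (pytype, fn))

    def _register_defaults(self) -> None:
        for name in ("int", "integer", "long"):
            self.register_parser(xsd(name), lambda t: int(t.strip()))
        for name in ("float", "double", "decimal"):
            self.register_parser(xsd(name), lambda t: float(t.strip()))
        self.register_parser(xsd("boolean"), _parse_boolean)
        self.register_parser(xsd("string"), lambda t: t)
        self.register_parser(xsd("anyURI"), lambda t: t.strip())
        array = Predicate(DATATYPE_NAMESPACE, "array", prefix="pdt")
        self.register_parser(array, parse_array_literal)

        # most recently registered wins; bool must precede int in the
        # isinstance search, so it is registered last
        self.register_formatter(
            (list, tuple),  # type: ignore[arg-type]
            lambda v: (format_array_literal(v),
                       Predicate(DATATYPE_NAMESPACE, "array", prefix="pdt")))
        self.register_formatter(str, lambda v: (v, xsd("string")))
        self.register_formatter(float, lambda v: (format_float(v), xsd("double")))
        self.register_formatter(int, lambda v: (str(v), xsd("integer")))
        self.register_formatter(bool, lambda v: ("true" if v else "false",
                                                 xsd("boolean")))

    def parse(self, text: str, datatype: Optional[Predicate]) -> Any:
        if datatype is None:
            return text
        fn = self._parsers.get(datatype.uri)
        if fn is None:
            return text
        try:
            return fn(text)
        except (ValueError, TypeError) as exc:
            raise FormatError(
                f"cannot parse {text!r} as {datatype.curie()}",
                code="TYPE_MISMATCH") from exc

    def format(self, value: Any) -> tuple[str, Predicate]:
        for pytype, fn in self._formatters:
            if isinstance(value, pytype):
                return fn(value)
        raise FormatError(f"no translator registered for {type(value).__name__}",
                          code="UNREGISTERED_TYPE")


def format_float(v: float) -> str:
    text = repr(v)
    return text


def format_array_literal(values: Iterable[Any]) -> str:
    """BEAST-style array rendering: ``{0.5,1.5}``."""
    parts = []
    for v in values:
        text, _ = DEFAULT_TRANSLATORS.format(v)
        parts.append(text)
    return "{" + ",".join(parts) + "}"


def parse_array_literal(text: str) -> list[Any]:
    inner = text.strip()
    if inner.startswith("{") and inner.endswith("}"):
        inner = inner[1:-1]
    if not inner:
        return []
    return [parse_scalar(part) for part in inner.split(",")]


_INT_RE = re.compile(r"[+-]?\d+$")
_FLOAT_RE = re.compile(r"[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def parse_scalar(text: str) -> Any:
    """Best-effort scalar typing for values without a declared datatype
    (hot comments): int, then float, else the string itself."""
    s = text.strip()
    if _INT_RE.match(s):
        return int(s)
    if _FLOAT_RE.match(s):
        return float(s)
    if s.startswith('"') and s.endswith('"') and len(s) >= 2:
        return s[1:-1]
    return s


DEFAULT_TRANSLATORS = LiteralValueTranslators()


def parse_literal(text: str, datatype: Optional[Predicate] = None,
                  translators: LiteralValueTranslators | None = None) -> Any:
    return (translators or DEFAULT_TRANSLATORS).parse(text, datatype)


def format_literal(value: Any,
                   translators: LiteralValueTranslators | None = None
                   ) -> tuple[str, Predicate]:
    return (translators or DEFAULT_TRANSLATORS).format(value)


# ---------------------------------------------------------------------------
# XML content bridging
# ---------------------------------------------------------------------------

XmlEvent = tuple  # ("start", tag, attrs) | ("chars", text) | ("end", tag)


def xml_fragment_to_events(fragment: str) -> list[XmlEvent]:
    """Expose an XML fragment as generic start/chars/end events, so existing
    XML-processing code can consume nested metadata content unchanged."""
    try:
        root = ET.fromstring(fragment)
    except ET.ParseError as exc:
        raise FormatError(f"malformed XML fragment: {exc}",
                          code="XML_SYNTAX") from exc
    events: list[XmlEvent] = []

    def walk(elem: ET.Element) -> None:
        events.append(("start", elem.tag, dict(elem.attrib)))
        if elem.text:
            events.append(("chars", elem.text))
        for child in elem:
            walk(child)
            if child.tail:
                events.append(("chars", child.tail))
        events.append(("end", elem.tag))

    walk(root)
    return events


def xml_events_to_fragment(events: Iterable[XmlEvent]) -> str:
    """Inverse of :func:`xml_fragment_to_events`; output is canonicalized."""
    stack: list[ET.Element] = []
    root: ET.Element | None = None
    last_closed: ET.Element | None = None
    for ev in events:
        kind = ev[0]
        if kind == "start":
            elem = ET.Element(ev[1], dict(ev[2]))
            if stack:
                stack[-1].append(elem)
            elif root is None:
                root = elem
            else:
                raise FormatError("multiple XML roots in content events",
                                  code="XML_SYNTAX")
            stack.append(elem)
            last_closed = None
        elif kind == "chars":
            if not stack:
                raise FormatError("character data outside XML element",
                                  code="XML_SYNTAX")
            if last_closed is not None:
                last_closed.tail = (last_closed.tail or "") + ev[1]
            else:
                stack[-1].text = (stack[-1].text or "") + ev[1]
        elif kind == "end":
            if not stack or stack[-1].tag != ev[1]:
                raise FormatError(f"unbalanced XML end tag {ev[1]!r}",
                                  code="XML_SYNTAX")
            last_closed = stack.pop()
        else:
            raise FormatError(f"unknown XML event kind {kind!r}",
                              code="XML_SYNTAX")
    if stack or root is None:
        raise FormatError("unterminated XML fragment", code="XML_SYNTAX")
    return canonical_xml(ET.tostring(root, encoding="unicode"))


def canonical_xml(text: str) -> str:
    return ET.canonicalize(text)


def xml_bridge(meta_events: Iterable[Event]) -> list[XmlEvent]:
    """Unpack the XML content events of one literal meta subsequence into
    generic XML events."""
    out: list[XmlEvent] = []
    for ev in meta_events:
        if ev.type is EventType.LITERAL_META_CONTENT:
            payload = ev.payload
            if isinstance(payload, LiteralContent) and payload.content_form == "xml":
                out.append(payload.value)
    return out


def pack_xml_events(events: Iterable[XmlEvent]) -> list[LiteralContent]:
    """Inverse bridge: pack generic XML events into literal content payloads."""
    events = list(events)
    xml_events_to_fragment(events)  # validates balance
    contents = [LiteralContent(ev, is_final=False, content_form="xml")
                for ev in events]
    if contents:
        contents[-1].is_final = True
    return contents


# ---------------------------------------------------------------------------
# Metadata trees (in-memory form used by writers)
# ---------------------------------------------------------------------------

@dataclass
class MetaNode:
    """One node of an annotation tree: a literal, a resource or a comment."""

    kind: str  # "literal" | "resource" | "comment"
    id: Optional[str] = None
    predicate: Optional[Predicate] = None
    string_key: Optional[str] = None
    datatype: Optional[Predicate] = None
    content_form: str = "simple"
    value: Any = None            # literal: assembled value / XML event list
    rel: Optional[Predicate] = None
    href: Optional[str] = None
    comment: Optional[str] = None
    children: list["MetaNode"] = field(default_factory=list)

    def effective_key(self) -> Optional[str]:
        if self.string_key is not None:
            return self.string_key
        pred = self.predicate if self.kind == "literal" else self.rel
        return derive_string_key(pred) if pred is not None else None

    def is_leaf_literal(self) -> bool:
        return self.kind == "literal"


def build_meta_tree(events: Iterable[Event]) -> list[MetaNode]:
    """Assemble a flat metadata event subsequence into annotation trees.

    The inverse of :func:`emit_meta_tree`: node count, predicates, values
    and order are preserved exactly.
    """
    roots: list[MetaNode] = []
    stack: list[MetaNode] = []

    def attach(node: MetaNode) -> None:
        (stack[-1].children if stack else roots).append(node)

    for ev in events:
        if ev.type is EventType.COMMENT:
            attach(MetaNode(kind="comment", comment=ev.payload))
        elif ev.type is EventType.LITERAL_META and ev.topology is Topology.START:
            info: LiteralMetaInfo = ev.payload
            node = MetaNode(kind="literal", id=ev.id, predicate=info.predicate,
                            string_key=info.string_key, datatype=info.datatype,
                            content_form=info.content_form,
                            value=[] if info.content_form == "xml" else None)
            attach(node)
            stack.append(node)
        elif ev.type is EventType.LITERAL_META_CONTENT:
            node = stack[-1]
            content: LiteralContent = ev.payload
            if node.content_form == "xml":
                node.value.append(content.value)
            elif node.value is None:
                node.value = content.value
            elif isinstance(node.value, str) and isinstance(content.value, str):
                node.value += content.value  # continued long value
            else:
                node.value = content.value
        elif ev.type is EventType.RESOURCE_META and ev.topology is Topology.START:
            rinfo: ResourceMetaInfo = ev.payload
            node = MetaNode(kind="resource", id=ev.id, rel=rinfo.rel,
                            href=rinfo.href, string_key=rinfo.string_key)
            attach(node)
            stack.append(node)
        elif ev.topology is Topology.END:
            if stack:
                stack.pop()
    return roots


def emit_meta_tree(nodes: Iterable[MetaNode], ids: IdSource) -> list[Event]:
    """Serialize annotation trees back into a metadata event subsequence."""
    out: list[Event] = []
    for node in nodes:
        if node.kind == "comment":
            out.append(sole(EventType.COMMENT, payload=node.comment))
        elif node.kind == "literal":
            info = LiteralMetaInfo(predicate=node.predicate,
                                   string_key=node.string_key,
                                   datatype=node.datatype,
                                   content_form=node.content_form)
            out.append(start(EventType.LITERAL_META,
                             id=node.id or ids.new(), payload=info))
            if node.content_form == "xml":
                contents = [LiteralContent(xe, is_final=False, content_form="xml")
                            for xe in (node.value or [])]
                if contents:
                    contents[-1].is_final = True
                for c in contents:
                    out.append(sole(EventType.LITERAL_META_CONTENT, payload=c))
            elif node.value is not None:
                out.append(sole(EventType.LITERAL_META_CONTENT,
                                payload=LiteralContent(node.value)))
            out.append(end(EventType.LITERAL_META))
        elif node.kind == "resource":
            rinfo = ResourceMetaInfo(rel=node.rel, href=node.href,
                                     string_key=node.string_key)
            out.append(start(EventType.RESOURCE_META,
                             id=node.id or ids.new(), payload=rinfo))
            out.extend(emit_meta_tree(node.children, ids))
            out.append(end(EventType.RESOURCE_META))
    return out


def leaf_literals(nodes: Iterable[MetaNode]) -> list[MetaNode]:
    """Lowest-level literal values of annotation trees — what survives in
    formats restricted to flat key=value annotations (hot comments,
    phyloXML property tags)."""
    found: list[MetaNode] = []
    for node in nodes:
        if node.kind == "literal":
            found.append(node)
        elif node.kind == "resource":
            found.extend(leaf_literals(node.children))
    return found


def simple_literal(predicate: Predicate | None = None,
                   string_key: str | None = None,
                   value: Any = None,
                   datatype: Predicate | None = None,
                   ids: IdSource | None = None) -> list[Event]:
    """Convenience: the three-event subsequence of one simple literal
    annotation (start, content, end)."""
    ids = ids or IdSource("m")
    node = MetaNode(kind="literal", predicate=predicate, string_key=string_key,
                    datatype=datatype, value=value)
    return emit_meta_tree([node], ids)
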