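"""Event vocabulary, stream grammar and consumption contracts.

A phylogenetic document (OTU lists, character matrices, trees, networks,
sets, metadata) is linearized into a stream of typed events.  Elements that
can contain nested content are represented by a START/END event pair;
atomic elements by a single SOLE event.  Every reader in this library
produces such a stream and every writer consumes one (through data
adapters), so the grammar enforced by :func:`validate_stream` is the
central contract of the package.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Callable, Iterable, Iterator, Optional


class Topology(Enum):
    SOLE = "SOLE"
    START = "START"
    END = "END"


class EventType(Enum):
    DOCUMENT = "DOCUMENT"
    OTU_LIST = "OTU_LIST"
    OTU = "OTU"
    ALIGNMENT = "ALIGNMENT"
    SEQUENCE = "SEQUENCE"
    SEQUENCE_TOKENS = "SEQUENCE_TOKENS"
    SINGLE_TOKEN = "SINGLE_TOKEN"
    CHARACTER_DEFINITION = "CHARACTER_DEFINITION"
    TOKEN_SET_DEFINITION = "TOKEN_SET_DEFINITION"
    TREE_NETWORK_GROUP = "TREE_NETWORK_GROUP"
    TREE = "TREE"
    NETWORK = "NETWORK"
    NODE = "NODE"
    EDGE = "EDGE"
    ROOT_EDGE = "ROOT_EDGE"
    OTU_SET = "OTU_SET"
    CHARACTER_SET = "CHARACTER_SET"
    TREE_NETWORK_SET = "TREE_NETWORK_SET"
    LITERAL_META = "LITERAL_META"
    LITERAL_META_CONTENT = "LITERAL_META_CONTENT"
    RESOURCE_META = "RESOURCE_META"
    COMMENT = "COMMENT"


#: Event types that occur only with SOLE topology; all others form START/END pairs.
SOLE_ONLY = frozenset(
    {
        EventType.SEQUENCE_TOKENS,
        EventType.SINGLE_TOKEN,
        EventType.LITERAL_META_CONTENT,
        EventType.COMMENT,
    }
)


@dataclass
class Event:
    """One element of the linear event stream.

    ``id`` is present on START and SOLE events of identifiable elements and
    is unique within a document.  ``linked_id`` refers to an ID emitted
    earlier in the stream (an alignment links its OTU list, a sequence its
    OTU, a tree node its OTU).  ``payload`` carries type-specific content:
    a token list for SEQUENCE_TOKENS, an :class:`EdgeInfo` for edges, the
    metadata payloads defined in :mod:`phylostream.meta`, interval lists for
    sets, and so on.  By the minimum-information rule the payload always
    suffices to process the event without resolving ``linked_id``.
    """

    type: EventType
    topology: Topology
    id: Optional[str] = None
    label: Optional[str] = None
    linked_id: Optional[str] = None
    payload: Any = None

    def is_start(self) -> bool:
        return self.topology is Topology.START

    def is_end(self) -> bool:
        return self.topology is Topology.END

    def __repr__(self) -> str:  # compact, used by the CLI event lister
        bits = [f"{self.type.value}.{self.topology.value}"]
        if self.id is not None:
            bits.append(f"id={self.id}")
        if self.label is not None:
            bits.append(f"label={self.label!r}")
        if self.linked_id is not None:
            bits.append(f"linked={self.linked_id}")
        if self.payload is not None:
            bits.append(f"payload={self.payload!r}")
        return "<" + " ".join(bits) + ">"


def start(etype: EventType, id: str, label: str | None = None,
          linked_id: str | None = None, payload: Any = None) -> Event:
    return Event(etype, Topology.START, id=id, label=label,
                 linked_id=linked_id, payload=payload)


def end(etype: EventType) -> Event:
    return Event(etype, Topology.END)


def sole(etype: EventType, payload: Any = None, id: str | None = None,
         label: str | None = None, linked_id: str | None = None) -> Event:
    return Event(etype, Topology.SOLE, id=id, label=label,
                 linked_id=linked_id, payload=payload)


@dataclass
class EdgeInfo:
    """Payload of EDGE/ROOT_EDGE start events.

    ``source_id`` is ``None`` for a root edge.  ``length`` is the branch
    length, if any.
    """

    source_id: Optional[str]
    target_id: str
    length: Optional[float] = None


class IdSource:
    """Generates document-unique event IDs ("e1", "e2", ...).

    Formats that carry real IDs (NeXML) bypass this and use them verbatim;
    :meth:`claim` reserves such an ID so generated ones never collide.
    """

    def __init__(self, prefix: str = "e"):
        self._prefix = prefix
        self._counter = itertools.count(1)
        self._claimed: set[str] = set()

    def new(self) -> str:
        while True:
            candidate = f"{self._prefix}{next(self._counter)}"
            if candidate not in self._claimed:
                self._claimed.add(candidate)
                return candidate

    def claim(self, value: str) -> str:
        self._claimed.add(value)
        return value


# ---------------------------------------------------------------------------
# Grammar validation
# ---------------------------------------------------------------------------

@dataclass
class Violation:
    position: int
    code: str
    message: str


@dataclass
class ValidationReport:
    valid: bool
    violations: list[Violation] = field(default_factory=list)
    warnings: list[Violation] = field(default_factory=list)


_META = {EventType.LITERAL_META, EventType.RESOURCE_META, EventType.COMMENT}

# Each container maps to ordered phases of allowed child types.  A child may
# appear in the current phase or any later one (which then becomes current);
# an earlier-phase child is an ordering violation.  COMMENT is legal in
# every phase of every container.
_PHASES: dict[EventType, list[frozenset[EventType]]] = {
    EventType.DOCUMENT: [
        frozenset(_META),
        frozenset({EventType.OTU_LIST, EventType.ALIGNMENT,
                   EventType.TREE_NETWORK_GROUP}),
    ],
    EventType.OTU_LIST: [
        frozenset(_META),
        frozenset({EventType.OTU}),
        frozenset({EventType.OTU_SET}),
    ],
    EventType.OTU: [frozenset(_META)],
    EventType.ALIGNMENT: [
        frozenset(_META),
        frozenset({EventType.CHARACTER_DEFINITION,
                   EventType.TOKEN_SET_DEFINITION}),
        frozenset({EventType.SEQUENCE}),
        frozenset({EventType.CHARACTER_SET}),
    ],
    EventType.SEQUENCE: [
        frozenset(_META | {EventType.SEQUENCE_TOKENS, EventType.SINGLE_TOKEN}),
    ],
    EventType.TREE_NETWORK_GROUP: [
        frozenset(_META),
        frozenset({EventType.TREE, EventType.NETWORK}),
        frozenset({EventType.TREE_NETWORK_SET}),
    ],
    EventType.TREE: [
        frozenset(_META),
        frozenset({EventType.NODE, EventType.EDGE, EventType.ROOT_EDGE}),
    ],
    EventType.NETWORK: [
        frozenset(_META),
        frozenset({EventType.NODE, EventType.EDGE, EventType.ROOT_EDGE}),
    ],
    EventType.NODE: [frozenset(_META)],
    EventType.EDGE: [frozenset(_META)],
    EventType.ROOT_EDGE: [frozenset(_META)],
    EventType.OTU_SET: [frozenset(_META)],
    EventType.CHARACTER_SET: [frozenset(_META)],
    EventType.TREE_NETWORK_SET: [frozenset(_META)],
    EventType.CHARACTER_DEFINITION: [frozenset(_META)],
    EventType.TOKEN_SET_DEFINITION: [frozenset(_META)],
    EventType.LITERAL_META: [
        frozenset({EventType.LITERAL_META_CONTENT, EventType.COMMENT}),
    ],
    EventType.RESOURCE_META: [frozenset(_META)],
}


class _Frame:
    __slots__ = ("etype", "phase", "nodes", "parents", "root_edges",
                 "edge_targets", "resource_children", "content_forms",
                 "has_href")

    def __init__(self, etype: EventType):
        self.etype = etype
        self.phase = 0
        self.has_href = False
        # tree/network bookkeeping
        self.nodes: set[str] = set()
        self.parents: dict[str, str] = {}
        self.root_edges = 0
        self.edge_targets: set[str] = set()
        # resource meta bookkeeping
        self.resource_children = 0
        # literal meta content form consistency
        self.content_forms: set[str] = set()


def validate_stream(events: Iterable[Event]) -> ValidationReport:
    """Check an event sequence against the stream grammar.

    Validates (a) the production rules (which children may occur where, in
    which order), (b) document-wide ID uniqueness, (c) that every
    ``linked_id`` and edge endpoint references a previously emitted ID, and
    (d) START/END balance.  Malformed streams yield ``valid=False`` with
    coded violations; no exception is raised.
    """
    report = ValidationReport(valid=True)

    def err(pos: int, code: str, message: str) -> None:
        report.valid = False
        report.violations.append(Violation(pos, code, message))

    def warn(pos: int, code: str, message: str) -> None:
        report.warnings.append(Violation(pos, code, message))

    seen_ids: set[str] = set()
    stack: list[_Frame] = []
    document_closed = False
    pos = -1

    for pos, ev in enumerate(events):
        if document_closed:
            err(pos, "TRAILING_EVENT", "event after DOCUMENT END")
            continue
        # topology discipline
        if ev.type in SOLE_ONLY and ev.topology is not Topology.SOLE:
            err(pos, "TOPOLOGY", f"{ev.type.value} must be SOLE")
            continue
        if ev.type not in SOLE_ONLY and ev.topology is Topology.SOLE:
            err(pos, "TOPOLOGY", f"{ev.type.value} must be START/END paired")
            continue

        if not stack:
            if ev.type is EventType.DOCUMENT and ev.topology is Topology.START:
                stack.append(_Frame(EventType.DOCUMENT))
                if ev.id is not None:
                    if ev.id in seen_ids:
                        err(pos, "DUPLICATE_ID", f"duplicate ID {ev.id!r}")
                    seen_ids.add(ev.id)
            else:
                err(pos, "OUTSIDE_DOCUMENT",
                    f"{ev.type.value} outside DOCUMENT")
            continue

        frame = stack[-1]

        if ev.topology is Topology.END:
            if ev.type is not frame.etype:
                err(pos, "UNBALANCED",
                    f"END {ev.type.value} closes open {frame.etype.value}")
                # attempt resync: pop until match or empty
                while stack and stack[-1].etype is not ev.type:
                    stack.pop()
                if stack:
                    stack.pop()
            else:
                if frame.etype is EventType.RESOURCE_META:
                    # empty resource metas are legal but suspicious
                    if frame.resource_children == 0 and not frame.has_href:
                        warn(pos, "EMPTY_RESOURCE",
                             "resource meta with neither href nor children")
                stack.pop()
            if not stack:
                document_closed = True
            continue

        # child event (START or SOLE) inside frame
        phases = _PHASES.get(frame.etype, [])
        placed = False
        for i in range(frame.phase, len(phases)):
            if ev.type in phases[i] or ev.type is EventType.COMMENT:
                frame.phase = i
                placed = True
                break
        if not placed:
            if any(ev.type in p for p in phases):
                err(pos, "GRAMMAR_ORDER",
                    f"{ev.type.value} out of order inside {frame.etype.value}")
            else:
                err(pos, "GRAMMAR_CHILD",
                    f"{ev.type.value} not allowed inside {frame.etype.value}")
                if ev.topology is Topology.START:
                    stack.append(_Frame(ev.type))
                continue

        if frame.etype is EventType.RESOURCE_META and ev.type is not EventType.COMMENT:
            frame.resource_children += 1

        # ID discipline
        if ev.id is not None:
            if ev.id in seen_ids:
                err(pos, "DUPLICATE_ID", f"duplicate ID {ev.id!r}")
            seen_ids.add(ev.id)
        if ev.linked_id is not None and ev.linked_id not in seen_ids:
            err(pos, "FORWARD_REFERENCE",
                f"linked_id {ev.linked_id!r} not emitted before position {pos}")

        # tree/network structural checks
        if ev.type in (EventType.EDGE, EventType.ROOT_EDGE):
            tframe = next((f for f in reversed(stack)
                           if f.etype in (EventType.TREE, EventType.NETWORK)),
                          None)
            info = ev.payload
            if tframe is not None and isinstance(info, EdgeInfo):
                if ev.type is EventType.ROOT_EDGE:
                    tframe.root_edges += 1
                    if tframe.root_edges > 1:
                        err(pos, "MULTIPLE_ROOT_EDGES",
                            "more than one root edge")
                for endpoint in (info.source_id, info.target_id):
                    if endpoint is not None and endpoint not in tframe.nodes:
                        err(pos, "FORWARD_REFERENCE",
                            f"edge endpoint {endpoint!r} not a previously "
                            f"emitted node of this tree/network")
                if tframe.etype is EventType.TREE and info.source_id is not None:
                    if info.target_id in tframe.edge_targets:
                        err(pos, "MULTIPLE_PARENTS",
                            f"node {info.target_id!r} has several incoming "
                            f"edges inside a TREE")
                    tframe.edge_targets.add(info.target_id)
                    # cycle detection by following the parent chain
                    tframe.parents[info.target_id] = info.source_id
                    hops, cur = 0, info.source_id
                    while cur is not None and hops <= len(tframe.parents):
                        if cur == info.target_id:
                            err(pos, "EDGE_CYCLE",
                                f"edge closes a cycle at {info.target_id!r}")
                            break
                        cur = tframe.parents.get(cur)
                        hops += 1
                elif tframe.etype is EventType.NETWORK and info.source_id is not None:
                    tframe.edge_targets.add(info.target_id)
            elif tframe is not None:
                err(pos, "MISSING_PAYLOAD", "edge event without EdgeInfo")
        if ev.type is EventType.NODE:
            tframe = next((f for f in reversed(stack)
                           if f.etype in (EventType.TREE, EventType.NETWORK)),
                          None)
            if tframe is not None and ev.id is not None:
                tframe.nodes.add(ev.id)

        # literal meta payload checks
        if ev.type is EventType.LITERAL_META:
            payload = ev.payload
            if payload is not None and getattr(payload, "predicate", None) is None \
                    and getattr(payload, "string_key", None) is None:
                err(pos, "META_UNIDENTIFIED",
                    "literal meta carries neither predicate nor string key")
        if ev.type is EventType.LITERAL_META_CONTENT and stack:
            lit = stack[-1]
            form = getattr(ev.payload, "content_form", None)
            if form is not None:
                lit.content_forms.add(form)
                if len(lit.content_forms) > 1:
                    err(pos, "MIXED_CONTENT_FORM",
                        "content events of one literal meta disagree in form")

        if ev.topology is Topology.START:
            child = _Frame(ev.type)
            if ev.type is EventType.RESOURCE_META:
                child.has_href = getattr(ev.payload, "href", None) is not None
            stack.append(child)

    if stack:
        report.valid = False
        report.violations.append(Violation(
            pos, "UNBALANCED",
            f"{len(stack)} element(s) left open at end of stream"))
    if pos == -1:
        report.valid = False
        report.violations.append(Violation(0, "EMPTY_STREAM", "no events"))
    return report


# ---------------------------------------------------------------------------
# Pull / push consumption
# ---------------------------------------------------------------------------

class PullReader:
    """Pull-mode wrapper around a reader's event generator.

    The caller controls advancement with :meth:`next` / iteration; the
    library never retains more than a tiny constant number of events
    between calls (``max_buffered`` instruments this for the streaming
    guarantee: memory stays O(1) in the document size).
    """

    def __init__(self, event_iter: Iterator[Event]):
        self._iter = iter(event_iter)
        self._buffer: deque[Event] = deque()
        self.max_buffered = 0
        self.closed = False

    def __iter__(self) -> Iterator[Event]:
        return self

    def __next__(self) -> Event:
        if self._buffer:
            return self._buffer.popleft()
        if self.closed:
            raise StopIteration
        try:
            return next(self._iter)
        except StopIteration:
            self.closed = True
            raise

    next = __next__

    def peek(self) -> Optional[Event]:
        if not self._buffer:
            if self.closed:
                return None
            try:
                self._buffer.append(next(self._iter))
            except StopIteration:
                self.closed = True
                return None
            self.max_buffered = max(self.max_buffered, len(self._buffer))
        return self._buffer[0]

    def close(self) -> None:
        self.closed = True
        close = getattr(self._iter, "close", None)
        if close is not None:
            close()


def push_dispatch(source: Iterable[Event],
                  listeners: list[Callable[[Event], None]]) -> None:
    """SAX-like push mode: deliver every event to every listener in order.

    Produces the same event sequence a pull loop over ``source`` would see.
    Listener exceptions abort the dispatch and propagate.
    """
    if not listeners:
        raise ValueError("push_dispatch requires at least one listener")
    for ev in source:
        for listener in listeners:
            listener(ev)


class PhyloStreamError(Exception):
    """Base class for all library errors."""


class FormatError(PhyloStreamError):
    """Fatal syntax or structural error in an input document."""

    def __init__(self, message: str, line: int | None = None,
                 column: int | None = None, code: str | None = None):
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", column {column}" if column is not None else "") + ")"
        super().__init__(message + loc)
        self.line = line
        self.column = column
        self.code = code


class WriteError(PhyloStreamError):
    """Raised when a document cannot be represented in the target format."""

    def __init__(self, message: str, code: str):
        super().__init__(message)
        self.code = code
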