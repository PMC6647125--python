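"""Application-facing data adapters used by all writers.

Writing cannot stream a single linear event sequence because each target
format needs the document's parts in its own order (NEXUS wants taxa before
characters, phyloXML only wants trees...).  Writers therefore pull event
*subsequences* from a family of adapter objects.  Applications with their
own data model implement the adapter protocol directly (true streaming);
:func:`events_to_adapter` additionally buffers a full event stream into
list-based adapters, which is what powers generic format conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Optional

from .events import (Event, EventType, PhyloStreamError, Topology,
                     validate_stream)

_META_TYPES = {EventType.LITERAL_META, EventType.RESOURCE_META,
               EventType.LITERAL_META_CONTENT, EventType.COMMENT}


@dataclass
class WarningEntry:
    code: str
    subject_id: Optional[str]
    detail: str


class WarningLog:
    """Ordered, machine-readable record of data loss and label edits.

    Writers log here instead of silently dropping content; the log never
    influences the written output itself.
    """

    def __init__(self) -> None:
        self.entries: list[WarningEntry] = []

    def warn(self, code: str, subject_id: Optional[str], detail: str) -> None:
        self.entries.append(WarningEntry(code, subject_id, detail))

    def codes(self) -> list[str]:
        return [e.code for e in self.entries]

    def count(self, code: str | None = None) -> int:
        if code is None:
            return len(self.entries)
        return sum(1 for e in self.entries if e.code == code)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[WarningEntry]:
        return iter(self.entries)


def warn(log: WarningLog, code: str, subject_id: Optional[str],
         detail: str) -> None:
    """Record one coded warning (module-level convenience)."""
    log.warn(code, subject_id, detail)


class Receiver:
    """Sink for event subsequences pulled from adapters.

    An optional ``accept`` predicate encodes the target format's capability
    profile: events it rejects are counted and warned about (with
    ``drop_code``), never silently lost.
    """

    def __init__(self, warning_log: WarningLog | None = None,
                 accept: Callable[[Event], bool] | None = None,
                 drop_code: str = "METADATA_DROPPED",
                 subject_id: Optional[str] = None):
        self.events: list[Event] = []
        self.warning_log = warning_log
        self.accept = accept
        self.drop_code = drop_code
        self.subject_id = subject_id
        self._drop_depth = 0

    def add(self, event: Event) -> None:
        if self._drop_depth > 0:
            # inside a dropped subtree: swallow without further warnings
            if event.topology is Topology.START:
                self._drop_depth += 1
            elif event.topology is Topology.END:
                self._drop_depth -= 1
            return
        if self.accept is not None and not self.accept(event):
            if self.warning_log is not None:
                self.warning_log.warn(
                    self.drop_code, self.subject_id or event.id,
                    f"{event.type.value} not representable in target format")
            if event.topology is Topology.START:
                self._drop_depth = 1
            return
        self.events.append(event)

    def add_all(self, events: Iterable[Event]) -> None:
        for ev in events:
            self.add(ev)


# ---------------------------------------------------------------------------
# Concrete list-based adapters
# ---------------------------------------------------------------------------

@dataclass
class ElementData:
    """A START event plus the nested content subsequence (without the END)."""

    start: Event
    content: list[Event] = field(default_factory=list)

    @property
    def id(self) -> str:
        return self.start.id

    @property
    def label(self) -> Optional[str]:
        return self.start.label

    def subsequence(self) -> list[Event]:
        return [self.start, *self.content,
                Event(self.start.type, Topology.END)]


class OTUListAdapter:
    def __init__(self, start: Event):
        self.start = start
        self.metadata: list[Event] = []
        self.otus: list[ElementData] = []
        self.otu_sets: list[ElementData] = []

    @property
    def id(self) -> str:
        return self.start.id

    def otu_ids(self) -> list[str]:
        return [o.id for o in self.otus]

    def get_otu_start_event(self, otu_id: str) -> Event:
        for o in self.otus:
            if o.id == otu_id:
                return o.start
        raise KeyError(otu_id)

    def write_metadata(self, receiver: Receiver) -> None:
        receiver.add_all(self.metadata)

    def events(self) -> Iterator[Event]:
        yield self.start
        yield from self.metadata
        for o in self.otus:
            yield from o.subsequence()
        for s in self.otu_sets:
            yield from s.subsequence()
        yield Event(EventType.OTU_LIST, Topology.END)


class MatrixAdapter:
    def __init__(self, start: Event):
        self.start = start
        self.metadata: list[Event] = []
        self.character_definitions: list[ElementData] = []
        self.token_sets: list[ElementData] = []
        #: token sets and character definitions in original stream order
        self.definitions: list[ElementData] = []
        self.sequences: dict[str, ElementData] = {}
        self.character_sets: list[ElementData] = []

    @property
    def id(self) -> str:
        return self.start.id

    @property
    def linked_otu_list(self) -> Optional[str]:
        return self.start.linked_id

    def sequence_ids(self) -> list[str]:
        return list(self.sequences)

    def get_sequence_start_event(self, seq_id: str) -> Event:
        return self.sequences[seq_id].start

    def sequence_tokens(self, seq_id: str) -> list[str]:
        tokens: list[str] = []
        for ev in self.sequences[seq_id].content:
            if ev.type is EventType.SEQUENCE_TOKENS:
                tokens.extend(ev.payload)
            elif ev.type is EventType.SINGLE_TOKEN:
                tokens.append(ev.payload)
        return tokens

    def sequence_length(self, seq_id: str) -> int:
        return len(self.sequence_tokens(seq_id))

    def sequence_metadata(self, seq_id: str) -> list[Event]:
        return [ev for ev in self.sequences[seq_id].content
                if ev.type in _META_TYPES]

    def write_sequence_content(self, receiver: Receiver, seq_id: str,
                               start: int = 0, end: int | None = None) -> None:
        """Serve a token range (plus interleaved metadata when the full
        range is requested) of one sequence to a receiver."""
        if start == 0 and end is None:
            receiver.add_all(self.sequences[seq_id].content)
            return
        tokens = self.sequence_tokens(seq_id)[start:end]
        receiver.add(Event(EventType.SEQUENCE_TOKENS, Topology.SOLE,
                           payload=tokens))

    def write_metadata(self, receiver: Receiver) -> None:
        receiver.add_all(self.metadata)

    def column_count(self) -> int:
        return max((self.sequence_length(s) for s in self.sequences), default=0)

    def events(self) -> Iterator[Event]:
        yield self.start
        yield from self.metadata
        for d in self.definitions:
            yield from d.subsequence()
        for s in self.sequences.values():
            yield from s.subsequence()
        for c in self.character_sets:
            yield from c.subsequence()
        yield Event(EventType.ALIGNMENT, Topology.END)


class TreeOrNetworkAdapter:
    def __init__(self, start: Event):
        self.start = start
        self.metadata: list[Event] = []
        self.nodes: dict[str, ElementData] = {}
        self.edges: list[ElementData] = []  # EDGE and ROOT_EDGE, stream order

    @property
    def id(self) -> str:
        return self.start.id

    @property
    def is_network(self) -> bool:
        return self.start.type is EventType.NETWORK

    def node_ids(self) -> list[str]:
        return list(self.nodes)

    def get_node_start_event(self, node_id: str) -> Event:
        return self.nodes[node_id].start

    def node_metadata(self, node_id: str) -> list[Event]:
        return self.nodes[node_id].content

    def root_edge(self) -> Optional[ElementData]:
        for e in self.edges:
            if e.start.type is EventType.ROOT_EDGE:
                return e
        return None

    def events(self) -> Iterator[Event]:
        yield self.start
        yield from self.metadata
        for n in self.nodes.values():
            yield from n.subsequence()
        for e in self.edges:
            yield from e.subsequence()
        yield Event(self.start.type, Topology.END)


class TreeNetworkGroupAdapter:
    def __init__(self, start: Event):
        self.start = start
        self.metadata: list[Event] = []
        self.members: list[TreeOrNetworkAdapter] = []
        self.sets: list[ElementData] = []

    @property
    def id(self) -> str:
        return self.start.id

    @property
    def linked_otu_list(self) -> Optional[str]:
        return self.start.linked_id

    def events(self) -> Iterator[Event]:
        yield self.start
        yield from self.metadata
        for m in self.members:
            yield from m.events()
        for s in self.sets:
            yield from s.subsequence()
        yield Event(EventType.TREE_NETWORK_GROUP, Topology.END)


class DocumentAdapter:
    """Main adapter handing writers the other adapters.

    Enumeration is repeatable: writers may iterate the members several
    times (NEXUS does one pass for TAXA and another for CHARACTERS) and
    receive identical content each time.
    """

    def __init__(self, start: Event | None = None):
        self.start = start or Event(EventType.DOCUMENT, Topology.START)
        self.document_metadata: list[Event] = []
        self.otu_lists: list[OTUListAdapter] = []
        self.matrices: list[MatrixAdapter] = []
        self.tree_network_groups: list[TreeNetworkGroupAdapter] = []

    def otu_list_by_id(self, list_id: str) -> Optional[OTUListAdapter]:
        for ol in self.otu_lists:
            if ol.id == list_id:
                return ol
        return None

    def all_trees_networks(self) -> list[TreeOrNetworkAdapter]:
        return [m for g in self.tree_network_groups for m in g.members]

    def events(self) -> Iterator[Event]:
        """Re-emit the buffered document as one full event stream."""
        yield self.start
        yield from self.document_metadata
        for ol in self.otu_lists:
            yield from ol.events()
        for m in self.matrices:
            yield from m.events()
        for g in self.tree_network_groups:
            yield from g.events()
        yield Event(EventType.DOCUMENT, Topology.END)


def events_to_adapter(events: Iterable[Event],
                      validate: bool = True) -> DocumentAdapter:
    """Buffer a full document event stream into list-based adapters.

    Composing ``read -> events_to_adapter -> write`` implements generic
    format conversion.  Invalid streams are rejected with the validator's
    report attached to the raised error.
    """
    events = list(events)
    if validate:
        report = validate_stream(events)
        if not report.valid:
            err = PhyloStreamError(
                "invalid event stream: "
                + "; ".join(f"{v.code}@{v.position}" for v in report.violations))
            err.report = report  # type: ignore[attr-defined]
            raise err

    doc = DocumentAdapter()
    it = iter(events)
    first = next(it, None)
    if first is None:
        return doc
    doc.start = first

    # stack entries: (container object, kind tag)
    stack: list[tuple[object, str]] = [(doc, "document")]

    def top_meta_sink() -> list[Event]:
        obj, kind = stack[-1]
        if kind == "document":
            return obj.document_metadata  # type: ignore[union-attr]
        return obj.metadata  # type: ignore[union-attr]

    def capture(into: list[Event]) -> None:
        # consume the rest of an open element's subtree, excluding its END
        depth = 1
        for sub in it:
            if sub.topology is Topology.END:
                depth -= 1
                if depth == 0:
                    return
            elif sub.topology is Topology.START:
                depth += 1
            into.append(sub)

    for ev in it:
        if ev.type is EventType.DOCUMENT and ev.topology is Topology.END:
            break
        obj, kind = stack[-1]

        if ev.type is EventType.OTU_LIST and ev.topology is Topology.START:
            ol = OTUListAdapter(ev)
            doc.otu_lists.append(ol)
            stack.append((ol, "otu_list"))
        elif ev.type is EventType.ALIGNMENT and ev.topology is Topology.START:
            m = MatrixAdapter(ev)
            doc.matrices.append(m)
            stack.append((m, "matrix"))
        elif ev.type is EventType.TREE_NETWORK_GROUP and ev.topology is Topology.START:
            g = TreeNetworkGroupAdapter(ev)
            doc.tree_network_groups.append(g)
            stack.append((g, "group"))
        elif ev.type in (EventType.TREE, EventType.NETWORK) \
                and ev.topology is Topology.START:
            t = TreeOrNetworkAdapter(ev)
            obj.members.append(t)  # type: ignore[union-attr]
            stack.append((t, "tree"))
        elif ev.topology is Topology.END and kind != "document":
            stack.pop()
        elif ev.type in _META_TYPES:
            sink = top_meta_sink()
            sink.append(ev)
            if ev.topology is Topology.START:
                # capture the whole meta subtree into the same sink,
                # including the closing END
                depth = 1
                for sub in it:
                    sink.append(sub)
                    if sub.topology is Topology.START:
                        depth += 1
                    elif sub.topology is Topology.END:
                        depth -= 1
                        if depth == 0:
                            break
        elif ev.topology is Topology.START:
            elem = ElementData(ev)
            capture(elem.content)
            _attach_element(obj, kind, elem)
        # SOLE non-meta events at container level do not occur in the grammar

    return doc


def _attach_element(obj: object, kind: str, elem: ElementData) -> None:
    etype = elem.start.type
    if kind == "otu_list":
        if etype is EventType.OTU:
            obj.otus.append(elem)  # type: ignore[union-attr]
        elif etype is EventType.OTU_SET:
            obj.otu_sets.append(elem)  # type: ignore[union-attr]
    elif kind == "matrix":
        if etype is EventType.SEQUENCE:
            obj.sequences[elem.start.id] = elem  # type: ignore[union-attr]
        elif etype is EventType.CHARACTER_DEFINITION:
            obj.character_definitions.append(elem)  # type: ignore[union-attr]
            obj.definitions.append(elem)  # type: ignore[union-attr]
        elif etype is EventType.TOKEN_SET_DEFINITION:
            obj.token_sets.append(elem)  # type: ignore[union-attr]
            obj.definitions.append(elem)  # type: ignore[union-attr]
        elif etype is EventType.CHARACTER_SET:
            obj.character_sets.append(elem)  # type: ignore[union-attr]
    elif kind == "group":
        if etype is EventType.TREE_NETWORK_SET:
            obj.sets.append(elem)  # type: ignore[union-attr]
    elif kind == "tree":
        if etype is EventType.NODE:
            obj.nodes[elem.start.id] = elem  # type: ignore[union-attr]
        elif etype in (EventType.EDGE, EventType.ROOT_EDGE):
            obj.edges.append(elem)  # type: ignore[union-attr]
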