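"""FASTA reading and writing.

Reading yields one alignment with one sequence per ``>`` record.  The text
after the first whitespace of a header line is stored as literal metadata
under the string key ``description``; ``;`` lines become comment events,
and optional integer column indices at the start of sequence lines are
recognized and stripped.  Written files are plain sequential records —
never with column indices, since downstream tools rarely accept them — and
FASTA carries no metadata, so every attached annotation is dropped with a
logged warning.
"""

from __future__ import annotations

import re
from typing import IO, Iterator

from ..adapters import DocumentAdapter, Receiver
from ..events import (Event, EventType, FormatError, Topology, WriteError,
                      end, sole, start)
from ..meta import simple_literal
from ._base import EventReader, EventWriter, WriteResult, iter_lines

_INDEXED_LINE = re.compile(r"^\s*(\d+)\s+(.*)$")


class FastaReader(EventReader):
    format_id = "fasta"

    def events(self) -> Iterator[Event]:
        allow_indices = self.params.get("allow_column_indices", True)
        yield start(EventType.DOCUMENT, self.ids.new())
        in_alignment = False
        in_sequence = False
        pending_comments: list[Event] = []

        for lineno, line in iter_lines(self.stream):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(";"):
                comment = sole(EventType.COMMENT, payload=stripped[1:].strip())
                if in_sequence:
                    yield comment
                else:
                    pending_comments.append(comment)
                continue
            if stripped.startswith(">"):
                if not in_alignment:
                    # comments before the first record are document-level
                    for c in pending_comments:
                        yield c
                    pending_comments = []
                    yield start(EventType.ALIGNMENT, self.ids.new())
                    in_alignment = True
                if in_sequence:
                    yield end(EventType.SEQUENCE)
                header = stripped[1:].strip()
                label, _, description = header.partition(" ")
                yield start(EventType.SEQUENCE, self.ids.new(),
                            label=label or None)
                in_sequence = True
                for c in pending_comments:
                    yield c
                pending_comments = []
                if description.strip():
                    yield from simple_literal(string_key="description",
                                              value=description.strip(),
                                              ids=self.ids)
                continue
            if not in_sequence:
                raise FormatError("sequence data before first '>' header",
                                  line=lineno, code="FASTA_SYNTAX")
            data = line
            if allow_indices:
                m = _INDEXED_LINE.match(line)
                if m:
                    data = m.group(2)
            tokens = [c for c in data if not c.isspace()]
            if tokens:
                yield sole(EventType.SEQUENCE_TOKENS, payload=tokens)

        for c in pending_comments:
            yield c
        if in_sequence:
            yield end(EventType.SEQUENCE)
        if in_alignment:
            yield end(EventType.ALIGNMENT)
        yield end(EventType.DOCUMENT)


class FastaWriter(EventWriter):
    format_id = "fasta"

    def write(self, document: DocumentAdapter, stream: IO[str],
              **params) -> WriteResult:
        line_length = params.get("line_length", 80)
        result = WriteResult()
        log = result.warnings

        for meta in _meta_subtrees(document.document_metadata):
            _warn_dropped(log, meta, None)
        for group in document.tree_network_groups:
            log.warn("CONTENT_DROPPED", group.id,
                     "trees/networks cannot be written to FASTA")
        for otu_list in document.otu_lists:
            # OTU lists are implicit in FASTA; only annotations are lost
            for meta in _meta_subtrees(otu_list.metadata):
                _warn_dropped(log, meta, otu_list.id)
            for otu in otu_list.otus:
                for meta in _meta_subtrees(otu.content):
                    _warn_dropped(log, meta, otu.id)

        for matrix in document.matrices:
            for meta in _meta_subtrees(matrix.metadata):
                _warn_dropped(log, meta, matrix.id)
            for elem in (matrix.character_definitions + matrix.token_sets
                         + matrix.character_sets):
                log.warn("CONTENT_DROPPED", elem.start.id,
                         f"{elem.start.type.value} not representable in FASTA")
            for seq_id in matrix.sequence_ids():
                seq_start = matrix.get_sequence_start_event(seq_id)
                label = seq_start.label or seq_id
                stream.write(f">{label}\n")
                receiver = Receiver()
                matrix.write_sequence_content(receiver, seq_id)
                tokens: list[str] = []
                meta_events: list[Event] = []
                for ev in receiver.events:
                    if ev.type is EventType.SEQUENCE_TOKENS:
                        tokens.extend(ev.payload)
                    elif ev.type is EventType.SINGLE_TOKEN:
                        tokens.append(ev.payload)
                    elif ev.type is EventType.COMMENT:
                        stream.write(f";{ev.payload}\n")
                    else:
                        meta_events.append(ev)
                for meta in _meta_subtrees(meta_events):
                    log.warn("METADATA_DROPPED", seq_id,
                             "FASTA does not support metadata")
                for token in tokens:
                    if len(token) != 1:
                        raise WriteError(
                            f"token {token!r} of sequence {label!r} is not a "
                            f"single character", code="UNWRITABLE_TOKEN")
                for i in range(0, len(tokens), line_length):
                    stream.write("".join(tokens[i:i + line_length]) + "\n")
        return result


def _meta_subtrees(meta_events: list[Event]):
    """Top-level annotation subtrees (their start/sole events only)."""
    depth = 0
    for ev in meta_events:
        if ev.topology is Topology.END:
            depth -= 1
        elif ev.topology is Topology.START:
            if depth == 0:
                yield ev
            depth += 1
        elif depth == 0 and ev.type is not EventType.COMMENT:
            yield ev


def _warn_dropped(log, meta_event: Event, subject_id) -> None:
    log.warn("METADATA_DROPPED", subject_id or meta_event.id,
             f"{meta_event.type.value} not representable in target format")
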