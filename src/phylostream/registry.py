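"""Format registry, content-based format guessing, and conversion.

Every reader and writer implements a common interface (strategy pattern)
and is reached through this registry, so application code can stay
format-agnostic: ``reader_for``/``writer_for`` build instances,
``guess_format`` sniffs the format from the first characters of the input,
and ``convert`` composes read → buffer → write for any supported pair.
Third-party formats can be registered at runtime.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import IO, Optional

from .adapters import DocumentAdapter, events_to_adapter
from .events import PhyloStreamError
from .formats._base import EventReader, EventWriter, Source, WriteResult
from .formats.fasta import FastaReader, FastaWriter
from .formats.mega import MegaReader
from .formats.newick import NewickReader, NewickWriter
from .formats.nexml import NexmlReader, NexmlWriter
from .formats.nexus import NexusReader, NexusWriter
from .formats.phylip import PhylipReader, PhylipWriter
from .formats.phyloxml import PhyloXmlReader, PhyloXmlWriter

UNKNOWN = "UNKNOWN"

#: content kinds used in capability profiles
OTU_LISTS = "otu_lists"
MATRICES = "matrices"
TREES = "trees"
NETWORKS = "networks"
SIMPLE_METADATA = "simple_metadata"
HIERARCHICAL_METADATA = "hierarchical_metadata"
SETS = "sets"

ALL_KINDS = frozenset({OTU_LISTS, MATRICES, TREES, NETWORKS, SIMPLE_METADATA,
                       HIERARCHICAL_METADATA, SETS})


@dataclass(frozen=True)
class FormatInfo:
    """Declares what a format can read, write, and represent.

    ``capability_profile`` lists the content kinds that survive writing;
    everything else is projected away with warnings, which is exactly what
    the round-trip tests assert.
    """

    format_id: str
    has_reader: bool
    has_writer: bool
    capability_profile: frozenset[str]
    reader_cls: Optional[type] = None
    writer_cls: Optional[type] = None


_REGISTRY: dict[str, FormatInfo] = {}


def register_format(info: FormatInfo) -> None:
    _REGISTRY[info.format_id] = info


def format_info(format_id: str) -> FormatInfo:
    try:
        return _REGISTRY[format_id]
    except KeyError:
        raise PhyloStreamError(
            f"UNKNOWN_FORMAT: no format registered as {format_id!r}") from None


def registered_formats() -> list[str]:
    return list(_REGISTRY)


def writable_formats() -> list[str]:
    return [f for f, info in _REGISTRY.items() if info.has_writer]


register_format(FormatInfo(
    "fasta", True, True, frozenset({MATRICES}),
    FastaReader, FastaWriter))
register_format(FormatInfo(
    "phylip", True, True, frozenset({MATRICES}),
    PhylipReader, PhylipWriter))
register_format(FormatInfo(
    "newick", True, True,
    frozenset({TREES, NETWORKS, SIMPLE_METADATA}),
    NewickReader, NewickWriter))
register_format(FormatInfo(
    "nexus", True, True,
    frozenset({OTU_LISTS, MATRICES, TREES, NETWORKS, SIMPLE_METADATA, SETS}),
    NexusReader, NexusWriter))
register_format(FormatInfo(
    "nexml", True, True, ALL_KINDS, NexmlReader, NexmlWriter))
register_format(FormatInfo(
    "phyloxml", True, True,
    frozenset({TREES, NETWORKS, SIMPLE_METADATA}),
    PhyloXmlReader, PhyloXmlWriter))
register_format(FormatInfo(
    "mega", True, False, frozenset({MATRICES, SIMPLE_METADATA, SETS}),
    MegaReader, None))


# ---------------------------------------------------------------------------
# Format guessing
# ---------------------------------------------------------------------------

_TWO_INTS = re.compile(r"^\s*\d+\s+\d+\s*$")
_XML_ROOT = re.compile(r"<\s*(?:[\w.-]+:)?([\w.-]+)([^>]*)>")


def guess_format(head: str) -> str:
    """Guess the format from the first characters of the input.

    Decision rules in priority order: an XML prolog or root element
    (namespace decides nexml vs phyloxml); the ``#NEXUS`` and ``#mega``
    magics; ``>`` or ``;`` as first non-blank character (FASTA); a header
    line of two integers (PHYLIP); ``(`` or a bare name followed by ``;``
    (Newick).  The input itself is never consumed: callers re-read from
    the start of the stream.
    """
    stripped = head.lstrip()
    if not stripped:
        return UNKNOWN
    if stripped.startswith("<"):
        for m in _XML_ROOT.finditer(stripped):
            name = m.group(1).lower()
            rest = m.group(2)
            if name in ("xml", "!--"):
                continue
            if name == "nexml" or "nexml.org" in rest:
                return "nexml"
            if name == "phyloxml" or "phyloxml" in rest.lower():
                return "phyloxml"
            return UNKNOWN
        return UNKNOWN
    low = stripped.lower()
    if low.startswith("#nexus"):
        return "nexus"
    if low.startswith("#mega"):
        return "mega"
    if stripped[0] in (">", ";"):
        return "fasta"
    first_line = stripped.splitlines()[0]
    if _TWO_INTS.match(first_line):
        return "phylip"
    if stripped[0] == "(":
        return "newick"
    # a bare name (no structural chars besides the final ';') ending in ';'
    if ";" in stripped:
        candidate = stripped.split(";", 1)[0]
        if candidate and not set(candidate) & set("<>()[]{}=\n"):
            return "newick"
    return UNKNOWN


def guess_format_from_stream(stream: IO[str], probe: int = 4096) -> str:
    """Sniff without destroying the stream: seekable streams are rewound,
    non-seekable input should be wrapped by the caller."""
    position = stream.tell()
    head = stream.read(probe)
    stream.seek(position)
    return guess_format(head)


# ---------------------------------------------------------------------------
# Instantiation and conversion
# ---------------------------------------------------------------------------

def reader_for(format_id: str, source: Source, **params) -> EventReader:
    info = format_info(format_id)
    if not info.has_reader or info.reader_cls is None:
        raise PhyloStreamError(
            f"UNKNOWN_FORMAT: {format_id!r} has no reader")
    return info.reader_cls(source, **params)


def writer_for(format_id: str) -> EventWriter:
    info = format_info(format_id)
    if not info.has_writer or info.writer_cls is None:
        raise PhyloStreamError(
            f"UNKNOWN_FORMAT: {format_id!r} has no writer")
    return info.writer_cls()


def read_document(source: Source, format: str = "auto",
                  **params) -> EventReader:
    """Open a reader on ``source`` (text content or text stream), sniffing
    the format when ``format="auto"``."""
    if format == "auto":
        if isinstance(source, str):
            format = guess_format(source[:4096])
        else:
            format = guess_format_from_stream(source)
        if format == UNKNOWN:
            raise PhyloStreamError("UNKNOWN_FORMAT: could not guess format")
    return reader_for(format, source, **params)


def write_document(format_id: str, adapter: DocumentAdapter,
                   stream: IO[str] | None = None,
                   **params) -> tuple[str, WriteResult]:
    """Write an adapter-backed document; returns (text, result).  When a
    stream is given the text is also written there."""
    writer = writer_for(format_id)
    buf = io.StringIO()
    result = writer.write(adapter, buf, **params)
    text = buf.getvalue()
    if stream is not None:
        stream.write(text)
    return text, result


def convert(source: Source, to_format: str, from_format: str = "auto",
            reader_params: dict | None = None,
            **writer_params) -> tuple[str, WriteResult]:
    """Read any supported format and write any other: the composition
    read → events_to_adapter → write."""
    reader = read_document(source, format=from_format,
                           **(reader_params or {}))
    adapter = events_to_adapter(reader.events())
    return write_document(to_format, adapter, **writer_params)
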