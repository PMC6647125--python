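"""Shared infrastructure for format readers and writers.

All readers and writers implement one common interface (strategy pattern):
a reader exposes ``events()`` — a lazy generator over the document's event
stream — plus a ``warnings`` log; a writer exposes
``write(document_adapter, stream, **params)`` returning a
:class:`WriteResult`.  Instances are interchangeable, which is what lets a
single consumer loop or the conversion pipeline drive every format.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterator, Optional, Union

from ..adapters import DocumentAdapter, WarningLog
from ..events import Event, IdSource, PullReader
from ..names import NameTranslationMap

Source = Union[str, IO[str]]


def as_text_stream(source: Source) -> IO[str]:
    """Readers accept either a text stream or a string holding the document
    content itself (never a path; opening files is the registry's job)."""
    if isinstance(source, str):
        return io.StringIO(source)
    return source


class EventReader:
    """Base class of all format readers."""

    format_id: str = ""

    def __init__(self, source: Source, **params):
        self.stream = as_text_stream(source)
        self.params = params
        self.ids = IdSource()
        self.warnings = WarningLog()

    def events(self) -> Iterator[Event]:  # pragma: no cover - abstract
        raise NotImplementedError

    def reader(self) -> PullReader:
        return PullReader(self.events())

    def __iter__(self) -> Iterator[Event]:
        return self.events()


@dataclass
class WriteResult:
    warnings: WarningLog = field(default_factory=WarningLog)
    name_map: Optional[NameTranslationMap] = None


class EventWriter:
    """Base class of all format writers."""

    format_id: str = ""

    def write(self, document: DocumentAdapter, stream: IO[str],
              **params) -> WriteResult:  # pragma: no cover - abstract
        raise NotImplementedError

    def write_to_string(self, document: DocumentAdapter,
                        **params) -> tuple[str, WriteResult]:
        buf = io.StringIO()
        result = self.write(document, buf, **params)
        return buf.getvalue(), result


def iter_lines(stream: IO[str]) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, line without trailing newline); accepts
    LF and CRLF endings."""
    for i, raw in enumerate(stream, start=1):
        yield i, raw.rstrip("\r\n")
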