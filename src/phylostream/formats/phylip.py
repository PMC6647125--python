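"""PHYLIP reading and writing.

Both the standard variant (fixed 10-character name column) and the relaxed
variant (whitespace-terminated names of configurable maximum length) are
read, each in sequential and interleaved layout; the dialect is an explicit
parameter rather than sniffed, because no reliable detection rule exists.
Writing always emits the sequential layout.  Names longer than the
dialect's limit are shortened through the unique-name machinery and the
old-to-new :class:`~phylostream.names.NameTranslationMap` is returned with
the result; metadata is dropped with warnings, as the format stores none.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterator

from ..adapters import DocumentAdapter
from ..events import (Event, EventType, FormatError, WriteError, end, sole,
                      start)
from ..names import shorten_names_unique
from ._base import EventReader, EventWriter, WriteResult, iter_lines
from .fasta import _meta_subtrees, _warn_dropped

STANDARD_NAME_LIMIT = 10


@dataclass
class PhylipDialect:
    variant: str = "standard"     # "standard" | "relaxed"
    layout: str = "sequential"    # "sequential" | "interleaved"
    name_limit: int = 64          # relaxed only; standard is fixed at 10

    def __post_init__(self) -> None:
        if self.variant not in ("standard", "relaxed"):
            raise ValueError(f"unknown PHYLIP variant {self.variant!r}")
        if self.layout not in ("sequential", "interleaved"):
            raise ValueError(f"unknown PHYLIP layout {self.layout!r}")
        if self.variant == "standard":
            self.name_limit = STANDARD_NAME_LIMIT

    @property
    def interleaved(self) -> bool:
        return self.layout == "interleaved"


class PhylipReader(EventReader):
    format_id = "phylip"

    def __init__(self, source, dialect: PhylipDialect | None = None, **params):
        super().__init__(source, **params)
        self.dialect = dialect or PhylipDialect(
            variant=params.get("variant", "standard"),
            layout=params.get("layout", "sequential"),
            name_limit=params.get("name_limit", 64),
        )

    def events(self) -> Iterator[Event]:
        lines = iter_lines(self.stream)
        header = None
        for lineno, line in lines:
            if line.strip():
                header = (lineno, line)
                break
        if header is None:
            raise FormatError("empty PHYLIP input: missing header",
                              code="PHYLIP_SYNTAX")
        parts = header[1].split()
        if len(parts) < 2:
            raise FormatError("PHYLIP header needs ntax and nchar",
                              line=header[0], code="PHYLIP_SYNTAX")
        try:
            ntax, nchar = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise FormatError("non-integer PHYLIP dimensions",
                              line=header[0], code="PHYLIP_SYNTAX") from exc

        yield start(EventType.DOCUMENT, self.ids.new())
        yield start(EventType.ALIGNMENT, self.ids.new())

        names: list[str] = []
        rows: list[list[str]] = []
        expecting_names = True
        cursor = 0  # next sequence receiving tokens (interleaved wrap-around)

        for lineno, line in lines:
            if not line.strip():
                continue
            if len(names) >= ntax and all(len(r) >= nchar for r in rows):
                break
            if expecting_names and len(names) < ntax:
                name, data = self._split_name(line, lineno)
                names.append(name)
                rows.append(self._tokens(data))
                if len(names) == ntax:
                    if self.dialect.interleaved:
                        expecting_names = False
                        cursor = 0
                elif not self.dialect.interleaved:
                    # sequential: keep feeding this sequence until full
                    while len(rows[-1]) < nchar:
                        nxt = next(lines, None)
                        if nxt is None:
                            break
                        _, cont = nxt
                        if not cont.strip():
                            continue
                        rows[-1].extend(self._tokens(cont))
            else:
                # interleaved continuation blocks cycle through sequences
                rows[cursor % ntax].extend(self._tokens(line))
                cursor += 1
        # sequential tail: the last named sequence may continue past the loop
        if not self.dialect.interleaved and rows and len(rows[-1]) < nchar:
            pass  # already exhausted input; mismatch reported below

        if len(names) != ntax:
            raise FormatError(
                f"expected {ntax} sequences, found {len(names)}",
                code="DIMENSION_MISMATCH")
        for name, row in zip(names, rows):
            if len(row) != nchar:
                raise FormatError(
                    f"sequence {name!r} has {len(row)} characters, "
                    f"expected {nchar}", code="DIMENSION_MISMATCH")
            yield start(EventType.SEQUENCE, self.ids.new(), label=name)
            if row:
                yield sole(EventType.SEQUENCE_TOKENS, payload=row)
            yield end(EventType.SEQUENCE)
        yield end(EventType.ALIGNMENT)
        yield end(EventType.DOCUMENT)

    def _split_name(self, line: str, lineno: int) -> tuple[str, str]:
        if self.dialect.variant == "standard":
            name = line[:STANDARD_NAME_LIMIT].rstrip()
            return name, line[STANDARD_NAME_LIMIT:]
        parts = line.split(None, 1)
        if not parts:
            raise FormatError("blank sequence line", line=lineno,
                              code="PHYLIP_SYNTAX")
        name = parts[0]
        if len(name) > self.dialect.name_limit:
            name = name[: self.dialect.name_limit]
        return name, parts[1] if len(parts) > 1 else ""

    @staticmethod
    def _tokens(text: str) -> list[str]:
        return [c for c in text if not c.isspace()]


class PhylipWriter(EventWriter):
    format_id = "phylip"

    def write(self, document: DocumentAdapter, stream: IO[str],
              **params) -> WriteResult:
        variant = params.get("variant", "standard")
        name_limit = (STANDARD_NAME_LIMIT if variant == "standard"
                      else params.get("name_limit", 64))
        result = WriteResult()
        log = result.warnings

        for meta in _meta_subtrees(document.document_metadata):
            _warn_dropped(log, meta, None)
        for group in document.tree_network_groups:
            log.warn("CONTENT_DROPPED", group.id,
                     "trees/networks cannot be written to PHYLIP")
        for otu_list in document.otu_lists:
            for meta in _meta_subtrees(otu_list.metadata):
                _warn_dropped(log, meta, otu_list.id)
            for otu in otu_list.otus:
                for meta in _meta_subtrees(otu.content):
                    _warn_dropped(log, meta, otu.id)

        matrices = document.matrices
        all_pairs: list[tuple[str, str]] = []
        for matrix in matrices:
            for meta in _meta_subtrees(matrix.metadata):
                _warn_dropped(log, meta, matrix.id)
            for elem in (matrix.character_definitions + matrix.token_sets
                         + matrix.character_sets):
                log.warn("CONTENT_DROPPED", elem.start.id,
                         f"{elem.start.type.value} not representable in PHYLIP")
            seq_ids = matrix.sequence_ids()
            tokens = {s: matrix.sequence_tokens(s) for s in seq_ids}
            lengths = {len(t) for t in tokens.values()}
            if len(lengths) > 1:
                raise WriteError("PHYLIP requires equal sequence lengths",
                                 code="UNALIGNED_MATRIX")
            nchar = lengths.pop() if lengths else 0
            labels = [matrix.get_sequence_start_event(s).label or s
                      for s in seq_ids]
            name_map = shorten_names_unique(labels, name_limit)
            all_pairs.extend(name_map.pairs)
            for old, new in name_map.pairs:
                if old != new:
                    log.warn("LABEL_EDITED", None,
                             f"{old!r} written as {new!r}")
            stream.write(f" {len(seq_ids)} {nchar}\n")
            for seq_id, written_label in zip(seq_ids, name_map.written()):
                for tok in tokens[seq_id]:
                    if len(tok) != 1:
                        raise WriteError(
                            f"token {tok!r} is not a single character",
                            code="UNWRITABLE_TOKEN")
                for meta in _meta_subtrees(matrix.sequence_metadata(seq_id)):
                    _warn_dropped(log, meta, seq_id)
                if variant == "standard":
                    stream.write(written_label.ljust(STANDARD_NAME_LIMIT))
                else:
                    stream.write(written_label + " ")
                stream.write("".join(tokens[seq_id]) + "\n")

        from ..names import NameTranslationMap
        result.name_map = NameTranslationMap(all_pairs)
        return result
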