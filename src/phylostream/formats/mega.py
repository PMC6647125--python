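"""MEGA format reading (the format is read-only in this library).

Supported statements: ``!Title`` and ``!Description`` (document-level
literal metadata under the string keys ``title``/``description``),
``#name`` sequence records (repeated records append, so interleaved data
is handled), the ``.`` identity marker (expanded against the first
sequence), and ``!Gene=``/``!Domain=``/``!Label`` statements, which become
character sets over the column ranges they span.  A gene or domain
statement marks columns from its position in the data to the next such
statement (or the end of the matrix).
"""

from __future__ import annotations

import re
from typing import Iterator

from ..events import (Event, EventType, FormatError, end, sole, start)
from ..meta import simple_literal
from ._base import EventReader, iter_lines

_STATEMENT = re.compile(r"^!(\w+)\s*(.*?);?\s*$")
_GENE_DOMAIN = re.compile(r"(Gene|Domain)\s*=\s*(\S+?);?$", re.IGNORECASE)


class MegaReader(EventReader):
    format_id = "mega"

    def events(self) -> Iterator[Event]:
        lines = iter_lines(self.stream)
        first = next(lines, None)
        if first is None or not first[1].strip().lower().startswith("#mega"):
            raise FormatError("missing #mega magic", line=1,
                              code="MEGA_SYNTAX")

        yield start(EventType.DOCUMENT, self.ids.new())

        doc_meta: list[tuple[str, str]] = []
        order: list[str] = []
        seqs: dict[str, list[str]] = {}
        current: str | None = None
        # (set name, start column) markers in encounter order
        markers: list[tuple[str, int]] = []
        label_sites: dict[str, list[int]] = {}
        block_start = 0  # column where the current interleaved block began

        def current_column() -> int:
            return len(seqs[order[0]]) if order else 0

        for lineno, line in lines:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("!"):
                m = _STATEMENT.match(stripped)
                if not m:
                    continue
                keyword, rest = m.group(1), m.group(2)
                low = keyword.lower()
                if low in ("title", "description"):
                    doc_meta.append((low, rest.rstrip(";").strip()))
                elif low in ("gene", "domain"):
                    value = rest.rstrip(";").strip().lstrip("=").strip()
                    markers.append((value.split()[0] if value else low,
                                    current_column()))
                elif low == "label":
                    # one character per matrix column of the current block;
                    # space and '_' mean "unlabeled column"
                    body = rest.rstrip(";")
                    for offset, ch in enumerate(body):
                        if not ch.isspace() and ch != "_":
                            label_sites.setdefault(ch, []).append(
                                block_start + offset)
                else:
                    # other statements (e.g., !Format) are ignored
                    continue
                # inline Gene=/Domain= inside other statements
                gm = _GENE_DOMAIN.search(stripped)
                if gm and low not in ("gene", "domain"):
                    markers.append((gm.group(2), current_column()))
                continue
            if stripped.startswith("#"):
                name = stripped[1:].split()[0]
                if order and name == order[0]:
                    block_start = current_column()
                if name not in seqs:
                    order.append(name)
                    seqs[name] = []
                current = name
                rest = stripped[1:].split(None, 1)
                if len(rest) > 1:
                    self._append_tokens(seqs, order, current, rest[1], lineno)
                continue
            if current is None:
                raise FormatError("sequence data before first '#name' record",
                                  line=lineno, code="MEGA_SYNTAX")
            self._append_tokens(seqs, order, current, stripped, lineno)

        for key, value in doc_meta:
            yield from simple_literal(string_key=key, value=value,
                                      ids=self.ids)
        yield start(EventType.ALIGNMENT, self.ids.new())
        for name in order:
            yield start(EventType.SEQUENCE, self.ids.new(), label=name)
            if seqs[name]:
                yield sole(EventType.SEQUENCE_TOKENS, payload=seqs[name])
            yield end(EventType.SEQUENCE)

        nchar = len(seqs[order[0]]) if order else 0
        for i, (name, begin) in enumerate(markers):
            stop = markers[i + 1][1] if i + 1 < len(markers) else nchar
            if stop > begin:
                yield start(EventType.CHARACTER_SET, self.ids.new(),
                            label=name, payload=[(begin, stop)])
                yield end(EventType.CHARACTER_SET)
        for ch, cols in sorted(label_sites.items()):
            intervals = _columns_to_intervals(cols)
            yield start(EventType.CHARACTER_SET, self.ids.new(),
                        label=f"label_{ch}", payload=intervals)
            yield end(EventType.CHARACTER_SET)
        yield end(EventType.ALIGNMENT)
        yield end(EventType.DOCUMENT)

    @staticmethod
    def _append_tokens(seqs: dict[str, list[str]], order: list[str],
                       name: str, text: str, lineno: int) -> None:
        reference = seqs[order[0]] if order else []
        row = seqs[name]
        for ch in text:
            if ch.isspace():
                continue
            if ch == ".":
                column = len(row)
                if name == order[0] or column >= len(reference):
                    raise FormatError(
                        "'.' identity marker without a reference token",
                        line=lineno, code="MEGA_SYNTAX")
                row.append(reference[column])
            else:
                row.append(ch)


def _columns_to_intervals(columns: list[int]) -> list[tuple[int, int]]:
    intervals: list[tuple[int, int]] = []
    for col in sorted(set(columns)):
        if intervals and intervals[-1][1] == col:
            intervals[-1] = (intervals[-1][0], col + 1)
        else:
            intervals.append((col, col + 1))
    return intervals
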