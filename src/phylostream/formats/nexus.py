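"""NEXUS reading and writing, built as a block/command handler framework.

Supported blocks: TAXA, CHARACTERS/DATA/UNALIGNED, TREES (with translation
tables), SETS (CHARSET/TAXSET/TREESET), the Mesquite TITLE/LINK extension,
the MrBayes MIXED datatype, and a custom NETWORKS block holding Extended
Newick definitions.  Handlers are looked up per (block, command) in a
registry that applications may extend or override; unknown blocks and
commands are skipped whole with a warning, never an error.  DISTANCES,
ASSUMPTIONS and NOTES are outside the supported set and fall through to
that tolerant skipping.

Because a SETS block annotates elements declared in earlier blocks, the
reader assembles the whole document before emitting its event stream;
set events are re-attached to their owning containers so the stream stays
grammar-conformant.

Internal coordinates are 0-based half-open everywhere; the 1-based
inclusive NEXUS ranges (including open ``a-.`` and stepped ``a-b\\3``
forms) are converted at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Callable, Iterator, Optional

from ..adapters import DocumentAdapter
from ..events import (Event, EventType, FormatError, WriteError, end,
                      sole, start)
from ..meta import MetaNode, ROOTED_PREDICATE, build_meta_tree
from ..names import NameTranslationMap, make_labels_unique
from ._base import EventReader, EventWriter, WriteResult
from .fasta import _meta_subtrees, _warn_dropped
from .newick import (parse_newick, resolve_enewick, serialize_network_enewick,
                     serialize_tree_newick, tokenize_newick)

_PUNCT = set(";=,(){}")
_QUOTES = {"'", '"'}


@dataclass
class NexusToken:
    kind: str            # "word" | "punct" | "comment"
    value: str
    line: int
    quoted: bool = False


class NexusTokenizer:
    """Lexer over NEXUS text: quoted/unquoted words ('' escape, '_' to
    space in unquoted words), punctuation, and bracket comments."""

    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.line = 1

    def _advance(self, n: int = 1) -> None:
        self.line += self.text.count("\n", self.pos, self.pos + n)
        self.pos += n

    def tokens(self) -> Iterator[NexusToken]:
        text = self.text
        n = len(text)
        while self.pos < n:
            c = text[self.pos]
            if c.isspace():
                self._advance()
            elif c in _PUNCT:
                tok = NexusToken("punct", c, self.line)
                self._advance()
                yield tok
            elif c == "[":
                depth, j = 1, self.pos + 1
                while j < n and depth:
                    if text[j] == "[":
                        depth += 1
                    elif text[j] == "]":
                        depth -= 1
                    j += 1
                if depth:
                    raise FormatError("unterminated comment", line=self.line,
                                      code="NEXUS_SYNTAX")
                tok = NexusToken("comment", text[self.pos + 1:j - 1], self.line)
                self._advance(j - self.pos)
                yield tok
            elif c in _QUOTES:
                quote = c
                j = self.pos + 1
                parts: list[str] = []
                while True:
                    if j >= n:
                        raise FormatError("unterminated quoted word",
                                          line=self.line, code="NEXUS_SYNTAX")
                    if text[j] == quote:
                        if j + 1 < n and text[j + 1] == quote:
                            parts.append(quote)
                            j += 2
                            continue
                        break
                    parts.append(text[j])
                    j += 1
                tok = NexusToken("word", "".join(parts), self.line, quoted=True)
                self._advance(j + 1 - self.pos)
                yield tok
            else:
                j = self.pos
                while j < n and not text[j].isspace() and text[j] not in _PUNCT \
                        and text[j] not in _QUOTES and text[j] != "[":
                    j += 1
                word = text[self.pos:j].replace("_", " ")
                tok = NexusToken("word", word, self.line)
                self._advance(j - self.pos)
                yield tok

    def raw_until_semicolon(self) -> str:
        """Capture raw text (keeping brackets, quotes, parentheses) up to
        and including the next command-terminating ';'.  Used for TREE and
        NETWORK commands whose payload is a Newick string."""
        text = self.text
        n = len(text)
        out = []
        while self.pos < n:
            c = text[self.pos]
            if c == "[":
                depth, j = 1, self.pos + 1
                while j < n and depth:
                    if text[j] == "[":
                        depth += 1
                    elif text[j] == "]":
                        depth -= 1
                    j += 1
                out.append(text[self.pos:j])
                self._advance(j - self.pos)
            elif c == "'":
                j = self.pos + 1
                while j < n:
                    if text[j] == "'":
                        if j + 1 < n and text[j + 1] == "'":
                            j += 2
                            continue
                        break
                    j += 1
                out.append(text[self.pos:j + 1])
                self._advance(j + 1 - self.pos)
            elif c == ";":
                self._advance()
                return "".join(out) + ";"
            else:
                out.append(c)
                self._advance()
        raise FormatError("command not terminated by ';'", line=self.line,
                          code="NEXUS_SYNTAX")


def tokenize_nexus(source) -> list[NexusToken]:
    text = source if isinstance(source, str) else source.read()
    tokenizer = NexusTokenizer(text)
    tokens = list(tokenizer.tokens())
    if not tokens or tokens[0].kind != "word" \
            or tokens[0].value.lower() != "#nexus":
        raise FormatError("missing #NEXUS magic", line=1, code="NEXUS_SYNTAX")
    return tokens


# ---------------------------------------------------------------------------
# Coordinate conversion
# ---------------------------------------------------------------------------

def nexus_ranges_to_intervals(entries: list[str], upper: int
                              ) -> list[tuple[int, int]]:
    """Convert NEXUS 1-based inclusive range words (``a``, ``a-b``, ``a-.``,
    ``a-b\\step``) into merged 0-based half-open intervals bounded by
    ``upper``."""
    columns: set[int] = set()
    for entry in entries:
        step = 1
        body = entry
        if "\\" in entry:
            body, _, step_text = entry.partition("\\")
            step = int(step_text)
        if "-" in body:
            first_text, _, last_text = body.partition("-")
            first = int(first_text)
            last = upper if last_text.strip() == "." else int(last_text)
        else:
            first = last = int(body)
        if first < 1 or last > upper:
            raise FormatError(
                f"range {entry!r} exceeds dimensions (1-{upper})",
                code="RANGE_OUT_OF_BOUNDS")
        columns.update(range(first - 1, last, step))
    intervals: list[tuple[int, int]] = []
    for col in sorted(columns):
        if intervals and intervals[-1][1] == col:
            intervals[-1] = (intervals[-1][0], col + 1)
        else:
            intervals.append((col, col + 1))
    return intervals


def intervals_to_nexus_ranges(intervals: list[tuple[int, int]]) -> str:
    parts = []
    for begin, stop in intervals:
        if stop == begin + 1:
            parts.append(str(begin + 1))
        else:
            parts.append(f"{begin + 1}-{stop}")
    return " ".join(parts)


# ---------------------------------------------------------------------------
# Reader
# ---------------------------------------------------------------------------

@dataclass
class _OtuListRecord:
    id: str
    title: Optional[str]
    events: list[Event] = field(default_factory=list)   # OTU subtrees
    labels: list[str] = field(default_factory=list)
    otu_ids: list[str] = field(default_factory=list)
    sets: list[Event] = field(default_factory=list)

    def label_to_id(self) -> dict[str, str]:
        return dict(zip(self.labels, self.otu_ids))


@dataclass
class _MatrixRecord:
    id: str
    title: Optional[str]
    linked_otus: Optional[_OtuListRecord]
    events: list[Event] = field(default_factory=list)
    nchar: int = 0
    sets: list[Event] = field(default_factory=list)


@dataclass
class _GroupRecord:
    id: str
    title: Optional[str]
    linked_otus: Optional[_OtuListRecord]
    events: list[Event] = field(default_factory=list)
    tree_ids: list[str] = field(default_factory=list)
    tree_names: list[str] = field(default_factory=list)
    sets: list[Event] = field(default_factory=list)


@dataclass
class BlockContext:
    block_type: str
    title: Optional[str] = None
    links: dict[str, str] = field(default_factory=dict)
    commands: dict[str, list] = field(default_factory=dict)
    rows: list[tuple[str, list[NexusToken]]] = field(default_factory=list)
    comments: list[str] = field(default_factory=list)


HandlerRegistry = dict[tuple[str, str], Callable]


class NexusReader(EventReader):
    """Reads a NEXUS document into the event stream.

    ``params``: ``translate_internal_nodes`` (bool, default False) applies
    the TREES translation lookup to internal node labels as well — off by
    default so integer support values are not mistaken for taxon indices.
    """

    format_id = "nexus"

    #: class-level (block, command) handler registry; instances copy it, so
    #: third-party handlers can be added globally or per reader.
    handlers: HandlerRegistry = {}

    def __init__(self, source, **params):
        super().__init__(source, **params)
        self.handlers = dict(type(self).handlers)
        self.otu_lists: list[_OtuListRecord] = []
        self.matrices: list[_MatrixRecord] = []
        self.groups: list[_GroupRecord] = []
        self.doc_comments: list[Event] = []
        self.element_order: list[tuple[str, object]] = []

    # -- main loop ----------------------------------------------------------

    def events(self) -> Iterator[Event]:
        text = self.stream.read()
        tokenizer = NexusTokenizer(text)
        token_iter = tokenizer.tokens()
        first = next(token_iter, None)
        if first is None or first.kind != "word" \
                or first.value.lower() != "#nexus":
            raise FormatError("missing #NEXUS magic", line=1,
                              code="NEXUS_SYNTAX")
        yield start(EventType.DOCUMENT, self.ids.new())

        while True:
            tok = next(token_iter, None)
            if tok is None:
                break
            if tok.kind == "comment":
                self.doc_comments.append(sole(EventType.COMMENT,
                                              payload=tok.value))
                continue
            if tok.kind == "word" and tok.value.lower() == "begin":
                name_tok = next(token_iter, None)
                if name_tok is None or name_tok.kind != "word":
                    raise FormatError("BEGIN without block name",
                                      line=tok.line, code="NEXUS_SYNTAX")
                block_name = name_tok.value.upper()
                semi = next(token_iter, None)
                if semi is None or semi.kind != "punct" or semi.value != ";":
                    raise FormatError("BEGIN not terminated by ';'",
                                      line=name_tok.line, code="NEXUS_SYNTAX")
                self._read_block(block_name, tokenizer, token_iter)
            # stray tokens between blocks are tolerated

        for c in self.doc_comments:
            yield c
        for kind, record in self.element_order:
            if kind == "otus":
                yield start(EventType.OTU_LIST, record.id, label=record.title)
                yield from record.events
                yield from record.sets
                yield end(EventType.OTU_LIST)
            elif kind == "matrix":
                yield start(EventType.ALIGNMENT, record.id,
                            label=record.title,
                            linked_id=record.linked_otus.id
                            if record.linked_otus else None)
                yield from record.events
                yield from record.sets
                yield end(EventType.ALIGNMENT)
            elif kind == "group":
                yield start(EventType.TREE_NETWORK_GROUP, record.id,
                            label=record.title,
                            linked_id=record.linked_otus.id
                            if record.linked_otus else None)
                yield from record.events
                yield from record.sets
                yield end(EventType.TREE_NETWORK_GROUP)
        yield end(EventType.DOCUMENT)

    # -- block scaffolding --------------------------------------------------

    _KNOWN_BLOCKS = {"TAXA", "CHARACTERS", "DATA", "UNALIGNED", "TREES",
                     "SETS", "NETWORKS"}

    def _read_block(self, block_name: str, tokenizer: NexusTokenizer,
                    token_iter: Iterator[NexusToken]) -> None:
        ctx = BlockContext(block_type=block_name)
        known = block_name in self._KNOWN_BLOCKS
        if not known:
            self.warnings.warn("UNKNOWN_BLOCK_SKIPPED", None,
                               f"block {block_name!r} skipped")
        while True:
            tok = next(token_iter, None)
            if tok is None:
                raise FormatError(f"block {block_name} not closed by END;",
                                  code="NEXUS_SYNTAX")
            if tok.kind == "comment":
                ctx.comments.append(tok.value)
                continue
            if tok.kind == "punct" and tok.value == ";":
                continue
            if tok.kind == "word" and tok.value.lower() in ("end", "endblock"):
                semi = next(token_iter, None)
                # tolerate missing ';' at end-of-file
                break
            command = tok.value.upper() if tok.kind == "word" else tok.value
            if not known:
                self._skip_command(tokenizer, token_iter, command)
                continue
            handler = self.handlers.get((block_name, command))
            if handler is None:
                handler = self.handlers.get((block_name, "*"))
            if handler is None:
                self._skip_command(tokenizer, token_iter, command)
                self.warnings.warn(
                    "UNKNOWN_COMMAND_SKIPPED", None,
                    f"command {command!r} in block {block_name} skipped")
                continue
            handler(self, ctx, tokenizer, token_iter)
        self._finish_block(ctx)

    def _skip_command(self, tokenizer, token_iter, command: str) -> None:
        for tok in token_iter:
            if tok.kind == "punct" and tok.value == ";":
                return

    @staticmethod
    def _command_tokens(token_iter) -> list[NexusToken]:
        toks: list[NexusToken] = []
        for tok in token_iter:
            if tok.kind == "punct" and tok.value == ";":
                return toks
            toks.append(tok)
        raise FormatError("command not terminated by ';'",
                          code="NEXUS_SYNTAX")

    # -- linking ------------------------------------------------------------

    def _find_otu_list(self, ctx: BlockContext) -> Optional[_OtuListRecord]:
        title = ctx.links.get("TAXA")
        if title is not None:
            for rec in self.otu_lists:
                if rec.title == title:
                    return rec
            raise FormatError(f"LINK TAXA={title!r} references an undeclared "
                              f"TITLE", code="UNRESOLVED_LINK")
        return self.otu_lists[-1] if self.otu_lists else None

    # -- block finalization -------------------------------------------------

    def _finish_block(self, ctx: BlockContext) -> None:
        finisher = getattr(self, f"_finish_{ctx.block_type.lower()}", None)
        if finisher is not None:
            finisher(ctx)

    def _finish_taxa(self, ctx: BlockContext) -> None:
        labels = ctx.commands.get("TAXLABELS", [])
        ntax = ctx.commands.get("NTAX")
        if ntax is not None and int(ntax) != len(labels):
            raise FormatError(
                f"DIMENSIONS NTAX={ntax} but {len(labels)} TAXLABELS",
                code="DIMENSION_MISMATCH")
        if len(set(labels)) != len(labels):
            dup = next(l for l in labels if labels.count(l) > 1)
            raise FormatError(f"duplicate taxon label {dup!r}",
                              code="DUPLICATE_TAXON")
        rec = _OtuListRecord(self.ids.new(), ctx.title)
        for comment in ctx.comments:
            rec.events.append(sole(EventType.COMMENT, payload=comment))
        for label in labels:
            otu_id = self.ids.new()
            rec.labels.append(label)
            rec.otu_ids.append(otu_id)
            rec.events.append(start(EventType.OTU, otu_id, label=label))
            rec.events.append(end(EventType.OTU))
        self.otu_lists.append(rec)
        self.element_order.append(("otus", rec))

    def _finish_characters(self, ctx: BlockContext) -> None:
        self._finish_matrix_block(ctx, aligned=True,
                                  new_taxa="NEWTAXA" in ctx.commands
                                  or ctx.block_type == "DATA")

    _finish_data = _finish_characters

    def _finish_unaligned(self, ctx: BlockContext) -> None:
        self._finish_matrix_block(ctx, aligned=False, new_taxa=True)

    def _finish_matrix_block(self, ctx: BlockContext, aligned: bool,
                             new_taxa: bool) -> None:
        fmt = ctx.commands.get("FORMAT", {})
        nchar = ctx.commands.get("NCHAR")
        nchar = int(nchar) if nchar is not None else None
        gap = fmt.get("GAP")
        missing = fmt.get("MISSING")
        matchchar = fmt.get("MATCHCHAR")
        tokens_mode = fmt.get("TOKENS", False) \
            or fmt.get("DATATYPE", "").upper() == "CONTINUOUS"
        equate = fmt.get("EQUATE", {})

        linked = self._find_otu_list(ctx)
        rows: list[tuple[str, list[str]]] = []
        order: dict[str, int] = {}
        for name, row_tokens in ctx.rows:
            tokens = []
            for tok in row_tokens:
                if tokens_mode or tok.quoted:
                    tokens.append(tok.value)
                else:
                    tokens.extend(tok.value)
            if name in order:
                rows[order[name]][1].extend(tokens)
            else:
                order[name] = len(rows)
                rows.append((name, tokens))

        # EQUATE substitution first, then MATCHCHAR against the first row
        if equate:
            rows = [(name, [equate.get(t, t) for t in tokens])
                    for name, tokens in rows]
        if matchchar is not None:
            reference = rows[0][1] if rows else []
            for idx, (name, tokens) in enumerate(rows):
                expanded = []
                for col, tok in enumerate(tokens):
                    if tok == matchchar:
                        if idx == 0 or col >= len(reference):
                            raise FormatError(
                                f"match character in row {name!r} without "
                                f"reference token", code="NEXUS_SYNTAX")
                        tok = reference[col]
                    expanded.append(tok)
                rows[idx] = (name, expanded)

        if aligned and nchar is not None:
            for name, tokens in rows:
                if len(tokens) != nchar:
                    raise FormatError(
                        f"sequence {name!r} has {len(tokens)} tokens, "
                        f"expected {nchar}", code="DIMENSION_MISMATCH")
        effective_nchar = nchar if nchar is not None else max(
            (len(t) for _, t in rows), default=0)

        if new_taxa and linked is None and rows:
            # DATA/UNALIGNED may declare taxa inline
            rec = _OtuListRecord(self.ids.new(), None)
            for name, _ in rows:
                otu_id = self.ids.new()
                rec.labels.append(name)
                rec.otu_ids.append(otu_id)
                rec.events.append(start(EventType.OTU, otu_id, label=name))
                rec.events.append(end(EventType.OTU))
            self.otu_lists.append(rec)
            self.element_order.append(("otus", rec))
            linked = rec

        matrix = _MatrixRecord(self.ids.new(), ctx.title, linked,
                               nchar=effective_nchar)
        for comment in ctx.comments:
            matrix.events.append(sole(EventType.COMMENT, payload=comment))

        datatype = fmt.get("DATATYPE", "STANDARD")
        mixed = fmt.get("MIXED")
        if mixed:
            for part_name, intervals in mixed:
                tsd = start(EventType.TOKEN_SET_DEFINITION, self.ids.new(),
                            label=part_name, payload={"intervals": intervals})
                matrix.events.append(tsd)
                matrix.events.append(end(EventType.TOKEN_SET_DEFINITION))
        else:
            symbols = fmt.get("SYMBOLS")
            payload = {"intervals": [(0, effective_nchar)]}
            if symbols:
                payload["tokens"] = {s: s for s in symbols.split()}
            matrix.events.append(start(EventType.TOKEN_SET_DEFINITION,
                                       self.ids.new(), label=datatype.upper(),
                                       payload=payload))
            matrix.events.append(end(EventType.TOKEN_SET_DEFINITION))

        label_map = linked.label_to_id() if linked else {}
        for name, tokens in rows:
            otu_id = label_map.get(name)
            if linked is not None and otu_id is None:
                raise FormatError(
                    f"sequence name {name!r} does not resolve to a taxon",
                    code="UNRESOLVED_TAXON")
            seq_id = self.ids.new()
            matrix.events.append(start(EventType.SEQUENCE, seq_id,
                                       label=name, linked_id=otu_id))
            if tokens:
                matrix.events.append(sole(EventType.SEQUENCE_TOKENS,
                                          payload=tokens))
            matrix.events.append(end(EventType.SEQUENCE))
        self.matrices.append(matrix)
        self.element_order.append(("matrix", matrix))

    def _finish_trees(self, ctx: BlockContext) -> None:
        linked = self._find_otu_list(ctx)
        table: dict[str, str] = ctx.commands.get("TRANSLATE", {})
        apply_internal = self.params.get("translate_internal_nodes", False)

        group = _GroupRecord(self.ids.new(), ctx.title, linked)
        for comment in ctx.comments:
            group.events.append(sole(EventType.COMMENT, payload=comment))

        label_map = linked.label_to_id() if linked else {}
        index_map = {str(i + 1): (label, label_map[label])
                     for i, label in enumerate(linked.labels)} if linked else {}

        def resolve(label: str, is_internal: bool):
            if is_internal and not apply_internal:
                return None
            # lookup order: TRANSLATE entry, taxon label, 1-based index
            if label in table:
                target = table[label]
                if target in label_map:
                    return target, label_map[target]
                return target, None
            if label in label_map:
                return label, label_map[label]
            if label in index_map:
                return index_map[label]
            if not is_internal and linked is not None:
                self.warnings.warn(
                    "UNRESOLVED_LABEL", None,
                    f"terminal node label {label!r} matches no taxon")
            return None

        for name, newick_text in ctx.commands.get("TREES", []):
            rooted_meta: list[MetaNode] = []
            body = newick_text.strip()
            m = re.match(r"^\s*\[&\s*([RU])\s*\]", body, re.IGNORECASE)
            if m:
                rooted_meta.append(MetaNode(
                    kind="literal", predicate=ROOTED_PREDICATE,
                    string_key="rooted",
                    value=m.group(1).upper() == "R"))
                body = body[m.end():]
            tokens = tokenize_newick(body)
            tree_id = self.ids.new()
            tree_events = parse_newick(tokens, self.ids, tree_id=tree_id,
                                       label=name,
                                       extra_tree_meta=rooted_meta or None,
                                       resolve_label=resolve)
            resolved = resolve_enewick(tree_events, self.warnings)
            group.events.extend(resolved)
            group.tree_ids.append(tree_id)
            group.tree_names.append(name)
        self.groups.append(group)
        self.element_order.append(("group", group))

    def _finish_networks(self, ctx: BlockContext) -> None:
        linked = self._find_otu_list(ctx)
        group = _GroupRecord(self.ids.new(), ctx.title, linked)
        for name, newick_text in ctx.commands.get("NETWORKS", []):
            tokens = tokenize_newick(newick_text.strip())
            tree_id = self.ids.new()
            tree_events = parse_newick(tokens, self.ids, tree_id=tree_id,
                                       label=name)
            group.events.extend(resolve_enewick(tree_events, self.warnings))
            group.tree_ids.append(tree_id)
            group.tree_names.append(name)
        self.groups.append(group)
        self.element_order.append(("group", group))

    def _finish_sets(self, ctx: BlockContext) -> None:
        for kind, name, entries in ctx.commands.get("SETS", []):
            if kind == "CHARSET":
                target = self._linked_matrix(ctx)
                if target is None:
                    raise FormatError("CHARSET without a character matrix",
                                      code="RANGE_OUT_OF_BOUNDS")
                intervals = nexus_ranges_to_intervals(entries, target.nchar)
                target.sets.append(start(EventType.CHARACTER_SET,
                                         self.ids.new(), label=name,
                                         payload=intervals))
                target.sets.append(end(EventType.CHARACTER_SET))
            elif kind == "TAXSET":
                target_list = self._find_otu_list(ctx)
                if target_list is None:
                    raise FormatError("TAXSET without a TAXA block",
                                      code="UNRESOLVED_TAXON")
                members = []
                label_map = target_list.label_to_id()
                for entry in entries:
                    if entry in label_map:
                        members.append(label_map[entry])
                    else:
                        for begin, stop in nexus_ranges_to_intervals(
                                [entry], len(target_list.otu_ids)):
                            members.extend(
                                target_list.otu_ids[begin:stop])
                target_list.sets.append(start(EventType.OTU_SET,
                                              self.ids.new(), label=name,
                                              payload=members))
                target_list.sets.append(end(EventType.OTU_SET))
            elif kind == "TREESET":
                group = self.groups[-1] if self.groups else None
                if group is None:
                    raise FormatError("TREESET without a TREES block",
                                      code="RANGE_OUT_OF_BOUNDS")
                members = []
                name_map = dict(zip(group.tree_names, group.tree_ids))
                for entry in entries:
                    if entry in name_map:
                        members.append(name_map[entry])
                    else:
                        for begin, stop in nexus_ranges_to_intervals(
                                [entry], len(group.tree_ids)):
                            members.extend(group.tree_ids[begin:stop])
                group.sets.append(start(EventType.TREE_NETWORK_SET,
                                        self.ids.new(), label=name,
                                        payload=members))
                group.sets.append(end(EventType.TREE_NETWORK_SET))

    def _linked_matrix(self, ctx: BlockContext) -> Optional[_MatrixRecord]:
        title = ctx.links.get("CHARACTERS")
        if title is not None:
            for rec in self.matrices:
                if rec.title == title:
                    return rec
            raise FormatError(
                f"LINK CHARACTERS={title!r} references an undeclared TITLE",
                code="UNRESOLVED_LINK")
        return self.matrices[-1] if self.matrices else None


# -- command handlers -------------------------------------------------------

def _handle_title(reader: NexusReader, ctx, tokenizer, token_iter) -> None:
    toks = reader._command_tokens(token_iter)
    if toks:
        ctx.title = toks[0].value


def _handle_link(reader: NexusReader, ctx, tokenizer, token_iter) -> None:
    toks = reader._command_tokens(token_iter)
    # LINK TAXA = title;
    words = [t for t in toks if t.kind == "word"]
    if len(words) >= 2:
        ctx.links[words[0].value.upper()] = words[1].value
    # eagerly validate TAXA links
    if "TAXA" in ctx.links:
        reader._find_otu_list(ctx)


def _handle_dimensions(reader: NexusReader, ctx, tokenizer, token_iter) -> None:
    # DIMENSIONS [NEWTAXA] NTAX=2 NCHAR=4;  ('=' arrives as a punct token)
    toks = reader._command_tokens(token_iter)
    pending = None
    for tok in toks:
        if tok.kind != "word":
            continue
        if tok.value.isdigit():
            if pending:
                ctx.commands[pending] = tok.value
                pending = None
        else:
            if pending:  # previous keyword had no value: a flag
                ctx.commands[pending] = True
            pending = tok.value.upper()
    if pending:
        ctx.commands[pending] = True


def _handle_taxlabels(reader: NexusReader, ctx, tokenizer, token_iter) -> None:
    toks = reader._command_tokens(token_iter)
    ctx.commands["TAXLABELS"] = [t.value for t in toks if t.kind == "word"]


def _handle_newtaxa_flag(reader, ctx, tokenizer, token_iter) -> None:
    ctx.commands["NEWTAXA"] = True
    # flag may share a DIMENSIONS command; treated as standalone word here


def _handle_format(reader: NexusReader, ctx, tokenizer, token_iter) -> None:
    toks = reader._command_tokens(token_iter)
    fmt: dict = {}
    i = 0
    while i < len(toks):
        tok = toks[i]
        if tok.kind != "word":
            i += 1
            continue
        key = tok.value.upper()
        # KEY = VALUE
        if i + 1 < len(toks) and toks[i + 1].kind == "punct" \
                and toks[i + 1].value == "=":
            if key == "DATATYPE" and i + 2 < len(toks) \
                    and toks[i + 2].value.upper() == "MIXED":
                parts, i = _parse_mixed(toks, i + 3, ctx, reader)
                fmt["DATATYPE"] = "MIXED"
                fmt["MIXED"] = parts
                continue
            value = toks[i + 2].value if i + 2 < len(toks) else ""
            if key == "EQUATE":
                fmt["EQUATE"] = _parse_equate(value)
            else:
                fmt[key] = value
            i += 3
        else:
            fmt[key] = True
            i += 1
    ctx.commands["FORMAT"] = fmt


def _parse_mixed(toks, i, ctx, reader):
    # MIXED ( dna:1-4 , standard:5-6 )
    parts: list[tuple[str, list[tuple[int, int]]]] = []
    if i < len(toks) and toks[i].kind == "punct" and toks[i].value == "(":
        i += 1
        while i < len(toks) and not (toks[i].kind == "punct"
                                     and toks[i].value == ")"):
            if toks[i].kind == "word":
                name, _, rng = toks[i].value.partition(":")
                upper = int(ctx.commands.get("NCHAR", 10 ** 9))
                parts.append((name.upper(),
                              nexus_ranges_to_intervals([rng], upper)))
            i += 1
        i += 1
    return parts, i


def _parse_equate(value: str) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for pair in value.split():
        key, sep, val = pair.partition("=")
        if sep:
            mapping[key] = val
    return mapping


def _handle_matrix(reader: NexusReader, ctx, tokenizer, token_iter) -> None:
    toks = reader._command_tokens(token_iter)
    # group tokens into physical rows by line number; first word of a row
    # is the taxon/sequence name
    rows: list[tuple[str, list[NexusToken]]] = []
    current_line = None
    for tok in toks:
        if tok.kind == "comment":
            ctx.comments.append(tok.value)
            continue
        if tok.line != current_line:
            current_line = tok.line
            rows.append((tok.value, []))
        else:
            rows[-1][1].append(tok)
    ctx.rows.extend(rows)


def _handle_translate(reader: NexusReader, ctx, tokenizer, token_iter) -> None:
    toks = reader._command_tokens(token_iter)
    table: dict[str, str] = {}
    entry: list[str] = []
    for tok in toks:
        if tok.kind == "punct" and tok.value == ",":
            if len(entry) >= 2:
                table[entry[0]] = entry[1]
            entry = []
        elif tok.kind == "word":
            entry.append(tok.value)
    if len(entry) >= 2:
        table[entry[0]] = entry[1]
    ctx.commands["TRANSLATE"] = table


def _handle_tree(reader: NexusReader, ctx, tokenizer, token_iter) -> None:
    # TREE name = <newick>;  — the Newick payload is captured raw
    name_tok = None
    for tok in token_iter:
        if tok.kind == "word":
            name_tok = tok
        elif tok.kind == "punct" and tok.value == "=":
            break
    raw = tokenizer.raw_until_semicolon()
    # re-synchronize the shared token iterator past the consumed raw text
    ctx.commands.setdefault("TREES", []).append(
        (name_tok.value if name_tok else None, raw))


def _handle_network(reader: NexusReader, ctx, tokenizer, token_iter) -> None:
    name_tok = None
    for tok in token_iter:
        if tok.kind == "word":
            name_tok = tok
        elif tok.kind == "punct" and tok.value == "=":
            break
    raw = tokenizer.raw_until_semicolon()
    ctx.commands.setdefault("NETWORKS", []).append(
        (name_tok.value if name_tok else None, raw))


def _make_set_handler(kind: str):
    def handler(reader: NexusReader, ctx, tokenizer, token_iter) -> None:
        toks = reader._command_tokens(token_iter)
        words = [t for t in toks if t.kind == "word"]
        puncts = [t for t in toks if t.kind == "punct"]
        if not words:
            return
        name = words[0].value
        entries = [t.value for t in words[1:]]
        ctx.commands.setdefault("SETS", []).append((kind, name, entries))
    return handler


NexusReader.handlers.update({
    ("TAXA", "TITLE"): _handle_title,
    ("TAXA", "DIMENSIONS"): _handle_dimensions,
    ("TAXA", "TAXLABELS"): _handle_taxlabels,
    ("SETS", "TITLE"): _handle_title,
    ("SETS", "LINK"): _handle_link,
    ("SETS", "CHARSET"): _make_set_handler("CHARSET"),
    ("SETS", "TAXSET"): _make_set_handler("TAXSET"),
    ("SETS", "TREESET"): _make_set_handler("TREESET"),
    ("TREES", "TITLE"): _handle_title,
    ("TREES", "LINK"): _handle_link,
    ("TREES", "TRANSLATE"): _handle_translate,
    ("TREES", "TREE"): _handle_tree,
    ("NETWORKS", "TITLE"): _handle_title,
    ("NETWORKS", "LINK"): _handle_link,
    ("NETWORKS", "NETWORK"): _handle_network,
})
for _block in ("CHARACTERS", "DATA", "UNALIGNED"):
    NexusReader.handlers.update({
        (_block, "TITLE"): _handle_title,
        (_block, "LINK"): _handle_link,
        (_block, "DIMENSIONS"): _handle_dimensions,
        (_block, "FORMAT"): _handle_format,
        (_block, "MATRIX"): _handle_matrix,
        (_block, "NEWTAXA"): _handle_newtaxa_flag,
    })


def register_handler(block: str, command: str, handler: Callable) -> None:
    """Extension point: add or replace a command handler globally."""
    NexusReader.handlers[(block.upper(), command.upper())] = handler


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------

_NEXUS_UNQUOTED = re.compile(r"^[^\s()\[\]{}/\\,;:=*'\"`+<>-]+$")


def _quote_nexus(label: str) -> str:
    if " " in label and _NEXUS_UNQUOTED.match(label.replace(" ", "x")) \
            and "_" not in label:
        return label.replace(" ", "_")
    if _NEXUS_UNQUOTED.match(label) and "_" not in label:
        return label
    return "'" + label.replace("'", "''") + "'"


class NexusWriter(EventWriter):
    format_id = "nexus"

    def write(self, document: DocumentAdapter, stream: IO[str],
              **params) -> WriteResult:
        result = WriteResult()
        log = result.warnings
        pairs: list[tuple[str, str]] = []
        stream.write("#NEXUS\n")

        for meta in _meta_subtrees(document.document_metadata):
            _warn_dropped(log, meta, None)

        multiple_lists = len(document.otu_lists) > 1
        list_titles: dict[str, str] = {}
        otu_labels: dict[str, str] = {}

        for i, otu_list in enumerate(document.otu_lists):
            for meta in _meta_subtrees(otu_list.metadata):
                _warn_dropped(log, meta, otu_list.id)
            labels = [o.label or o.id for o in otu_list.otus]
            name_map = make_labels_unique(labels)
            pairs.extend(name_map.pairs)
            for old, new in name_map.pairs:
                if old != new:
                    log.warn("LABEL_EDITED", otu_list.id,
                             f"{old!r} written as {new!r}")
            for otu, written in zip(otu_list.otus, name_map.written()):
                otu_labels[otu.id] = written
                for meta in _meta_subtrees(otu.content):
                    _warn_dropped(log, meta, otu.id)
            title = otu_list.start.label or f"taxa{i + 1}"
            list_titles[otu_list.id] = title
            stream.write("BEGIN TAXA;\n")
            if multiple_lists:
                stream.write(f"TITLE {_quote_nexus(title)};\n")
            stream.write(f"DIMENSIONS NTAX={len(labels)};\n")
            stream.write("TAXLABELS "
                         + " ".join(_quote_nexus(l)
                                    for l in name_map.written())
                         + ";\n")
            stream.write("END;\n")
            self._write_otu_sets(stream, otu_list, otu_labels)

        for matrix in document.matrices:
            for meta in _meta_subtrees(matrix.metadata):
                _warn_dropped(log, meta, matrix.id)
            seq_ids = matrix.sequence_ids()
            lengths = {matrix.sequence_length(s) for s in seq_ids}
            aligned = len(lengths) <= 1
            nchar = matrix.column_count()
            labels = []
            for s in seq_ids:
                ev = matrix.get_sequence_start_event(s)
                if ev.linked_id and ev.linked_id in otu_labels:
                    labels.append(otu_labels[ev.linked_id])
                else:
                    labels.append(ev.label or s)
                for meta in _meta_subtrees(matrix.sequence_metadata(s)):
                    _warn_dropped(log, meta, s)
            name_map = make_labels_unique(labels)
            pairs.extend(name_map.pairs)
            for old, new in name_map.pairs:
                if old != new:
                    log.warn("LABEL_EDITED", matrix.id,
                             f"{old!r} written as {new!r}")
            block = "CHARACTERS" if aligned else "UNALIGNED"
            stream.write(f"BEGIN {block};\n")
            if matrix.start.label:
                stream.write(f"TITLE {_quote_nexus(matrix.start.label)};\n")
            if multiple_lists and matrix.linked_otu_list:
                stream.write(
                    "LINK TAXA = "
                    f"{_quote_nexus(list_titles[matrix.linked_otu_list])};\n")
            if aligned:
                stream.write(f"DIMENSIONS NTAX={len(seq_ids)} "
                             f"NCHAR={nchar};\n")
            else:
                stream.write(f"DIMENSIONS NTAX={len(seq_ids)};\n")
            datatype = "STANDARD"
            if matrix.token_sets:
                label = (matrix.token_sets[0].start.label or "").upper()
                if label in ("DNA", "RNA", "PROTEIN", "STANDARD",
                             "CONTINUOUS", "NUCLEOTIDE"):
                    datatype = label
            tokens_mode = any(
                len(tok) > 1
                for s in seq_ids for tok in matrix.sequence_tokens(s))
            fmt = f"FORMAT DATATYPE={datatype} GAP=- MISSING=?"
            if tokens_mode:
                fmt += " TOKENS"
            stream.write(fmt + ";\n")
            for elem in matrix.character_definitions:
                log.warn("CONTENT_DROPPED", elem.start.id,
                         "character definitions are not written to NEXUS")
            stream.write("MATRIX\n")
            width = max((len(_quote_nexus(l)) for l in name_map.written()),
                        default=0)
            for s, written in zip(seq_ids, name_map.written()):
                toks = matrix.sequence_tokens(s)
                if tokens_mode:
                    data = " ".join(toks)
                else:
                    for tok in toks:
                        if len(tok) != 1:
                            raise WriteError(
                                f"token {tok!r} is not a single character",
                                code="UNWRITABLE_TOKEN")
                    data = "".join(toks)
                stream.write(f"{_quote_nexus(written).ljust(width)}  {data}\n")
            stream.write(";\n")
            stream.write("END;\n")
            self._write_charsets(stream, matrix, log)

        for group in document.tree_network_groups:
            for meta in _meta_subtrees(group.metadata):
                _warn_dropped(log, meta, group.id)
            trees = [m for m in group.members if not m.is_network]
            networks = [m for m in group.members if m.is_network]
            if trees:
                stream.write("BEGIN TREES;\n")
                if multiple_lists and group.linked_otu_list:
                    stream.write(
                        "LINK TAXA = "
                        f"{_quote_nexus(list_titles[group.linked_otu_list])};\n")
                for i, tree in enumerate(trees):
                    rooted_prefix = ""
                    tree_meta = build_meta_tree(tree.metadata)
                    kept: list[MetaNode] = []
                    for node in tree_meta:
                        if node.kind == "literal" and node.predicate is not None \
                                and node.predicate.uri == ROOTED_PREDICATE.uri:
                            rooted_prefix = "[&R] " if node.value else "[&U] "
                        elif node.kind != "comment":
                            log.warn("METADATA_DROPPED", tree.id,
                                     "tree-level metadata not representable "
                                     "in NEXUS")
                    name = tree.start.label or f"tree{i + 1}"
                    text = serialize_tree_newick(
                        tree, log,
                        metadata_style=params.get("metadata_style",
                                                  "KEY_VALUE"),
                        label_for_node=lambda n: (
                            otu_labels.get(n.start.linked_id, n.start.label)
                            if n.start.linked_id else n.start.label))
                    stream.write(f"TREE {_quote_nexus(name)} = "
                                 f"{rooted_prefix}{text}\n")
                stream.write("END;\n")
                self._write_treesets(stream, group, log)
            if networks:
                stream.write("BEGIN NETWORKS;\n")
                if multiple_lists and group.linked_otu_list:
                    stream.write(
                        "LINK TAXA = "
                        f"{_quote_nexus(list_titles[group.linked_otu_list])};\n")
                for i, network in enumerate(networks):
                    name = network.start.label or f"network{i + 1}"
                    text = serialize_network_enewick(
                        network, log,
                        metadata_style=params.get("metadata_style",
                                                  "KEY_VALUE"))
                    stream.write(f"NETWORK {_quote_nexus(name)} = {text}\n")
                stream.write("END;\n")

        result.name_map = NameTranslationMap(pairs)
        return result

    @staticmethod
    def _write_otu_sets(stream, otu_list, otu_labels) -> None:
        if not otu_list.otu_sets:
            return
        # TAXSETs follow their TAXA block in a SETS block of their own
        stream.write("BEGIN SETS;\n")
        for s in otu_list.otu_sets:
            members = s.start.payload or []
            labels = " ".join(_quote_nexus(otu_labels[m]) for m in members
                              if m in otu_labels)
            stream.write(f"TAXSET {_quote_nexus(s.start.label or s.start.id)}"
                         f" = {labels};\n")
        stream.write("END;\n")

    def _write_charsets(self, stream, matrix, log) -> None:
        if not matrix.character_sets:
            return
        stream.write("BEGIN SETS;\n")
        for s in matrix.character_sets:
            intervals = s.start.payload or []
            stream.write(
                f"CHARSET {_quote_nexus(s.start.label or s.start.id)} = "
                f"{intervals_to_nexus_ranges(intervals)};\n")
        stream.write("END;\n")

    @staticmethod
    def _write_treesets(stream, group, log) -> None:
        if not group.sets:
            return
        names = {m.id: (m.start.label or m.id) for m in group.members}
        stream.write("BEGIN SETS;\n")
        for s in group.sets:
            members = s.start.payload or []
            labels = " ".join(_quote_nexus(names[m]) for m in members
                              if m in names)
            stream.write(f"TREESET {_quote_nexus(s.start.label or s.start.id)}"
                         f" = {labels};\n")
        stream.write("END;\n")
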