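# Methods

This note records the model behind `phylostream`, the choices made where
the design space was genuinely open, and what the test evidence does and
does not show.

## The event stream and its grammar

The central abstraction is a linearization of a hierarchical phylogenetic
document into a flat sequence of typed events.  Twenty-two event types
cover documents, OTU lists and OTUs, alignments with sequences, token-set
and character (column) definitions, tree/network groups with trees,
networks, nodes and edges, three kinds of element sets, literal and
resource metadata, and comments.  Four types are atomic (`SOLE` only):
sequence token blocks, single tokens, literal-meta content, and comments;
all others are `START`/`END` pairs whose interior carries their content.

The grammar, in outline (Meta ::= literal | resource | comment, nesting
recursively; comments legal in every position where metadata is):

```
Document   ::= DOC_START Meta* (OTUList | Matrix | TreeNetworkGroup)* DOC_END
OTUList    ::= OL_START Meta* OTU* OTUSet* OL_END
Matrix     ::= AL_START Meta* (CharDef | TokenSetDef)* Sequence* CharSet* AL_END
Sequence   ::= SEQ_START (Meta | TOKENS | SINGLE_TOKEN)* SEQ_END
Group      ::= TNG_START Meta* (Tree | Network)* TreeNetworkSet* TNG_END
Tree/Net   ::= T_START Meta* (Node | Edge | RootEdge)* T_END
```

`validate_stream` checks these productions plus four global rules:
document-wide ID uniqueness; every `linked_id` and edge endpoint refers to
an ID emitted *earlier* (the application never needs look-ahead); START/END
balance; and per-tree structure (at most one incoming edge per node, no
cycles, at most one root edge — networks relax the in-degree rule).
Violations are returned as coded records, never exceptions, so the
validator can serve as a diagnostic on malformed streams.  Element sets
are constrained to follow their member elements; the alternative
(interleaving) was rejected because it forces consumers to buffer.

Two stream details are normative for this library: reader-generated IDs
are `"e"` plus a per-document counter unless the source format carries
real IDs (NeXML), which are used verbatim (all source IDs are claimed
before any ID is generated, so the two can never collide); and each event
carries enough payload to be processed without dereferencing its
`linked_id` (the minimum-information rule) — an edge event, for example,
embeds both endpoint IDs and its branch length.

## Consumption: pull, push, and the O(1) claim

Readers are generators; `PullReader` wraps them with a peek buffer and an
instrumented `max_buffered` counter, and `push_dispatch` drives any number
of listeners from the same stream (the two modes see element-wise
identical sequences — tested).  Text readers consume input line by line,
so a consumer that stops early reads at most one line beyond its last
event.  The streaming test pushes a 10⁶-token alignment through a
discarding consumer and asserts the retained-event counter never exceeds
one: memory is O(1) in document size, versus O(n) for any
document-object-model approach.  Two readers deliberately trade this
laziness for correctness, and buffer whole documents: NEXUS (a later SETS
block annotates earlier blocks, and emitting grammar-conformant streams
requires re-attaching sets to their containers) and the two XML formats
(parsed with `xml.etree`).  The constant-memory guarantee is therefore a
property of the FASTA/PHYLIP/Newick paths and of the event interface
itself, not of every reader.

## The metadata model

Annotations form trees: resource nodes (an RDF predicate `rel`, an
optional `href`, nested children) and literal leaves (predicate and/or
free string key, optional XSD datatype, a typed value).  The dual
predicate/string-key identification resolves the mismatch between
NeXML-style CURIE predicates and BEAST/MrBayes-style free identifiers:
when a format needs a string key and none is present, the predicate's
local part is used (`derive_string_key`).  Literal values are translated
by a registry of datatype translators (defaults: XSD string, boolean,
int/integer/long, float/double/decimal, anyURI, plus an internal array
datatype rendered BEAST-style as `{0.5,1.5}`); the registry is extensible
with custom types.  Arrays are carried as a single content event rather
than one event per element — the simplest faithful mapping of the
hot-comment array syntax.  XML-valued literals are carried as sequences of
generic start/chars/end XML events; `xml_bridge`/`pack_xml_events` convert
between that representation and text fragments so existing XML-processing
code can be reused unchanged, with canonicalized round trips.

Internal predicate namespaces (stable but arbitrary — any consistent
choice works, since they only ever meet their own inverse mapping):
`https://phylostream.example/predicates/phyloxml/` + element path for
phyloXML's fixed vocabulary (e.g. `taxonomy/id`, `confidence`),
`.../predicates/stringKeys/` for string-key-only literals that must
travel through NeXML's `property` attribute, and
`.../predicates/internal/` for rootedness.  Free-text comments pass
through NeXML as literals under the reserved string key `comment`, which
is therefore not available as a user key.

## Format notes

**FASTA** — description text after the first header whitespace is stored
as literal metadata under `description` rather than kept in the label;
`;` lines are comments; optional leading column indices on sequence lines
are recognized on reading and never written.  **PHYLIP** — standard
(10-character name field) and relaxed (whitespace-delimited names)
variants, each sequential or interleaved, selected explicitly by a
dialect parameter because no reliable sniffing rule exists; writing is
always sequential.  **MEGA** (read-only) — `!Title`/`!Description` become
document metadata; `.` copies the first sequence's token;
`!Gene=`/`!Domain=` statements mark character sets from their column
position to the next marker; `!Label` bodies are read positionally, one
character per column of the current block.

**Newick** — nodes are emitted in post-order, edges after both endpoints;
a length on the outermost element becomes a root edge.  Hot comments
before a `:` annotate the node, after it the branch — the dominant
convention of BEAST-era tree annotations, fixed here because the formats
themselves do not state it.  NHX keys map onto the internal phyloXML
predicates (S→`taxonomy/scientific_name`, T→`taxonomy/id`,
B→`confidence`, AC/GN→sequence fields); key-value comments parse scalars
and `{…}` arrays with best-effort typing (int, then float, else string).
Unparseable comment interiors degrade to plain comment events, never
errors.  Writers flatten annotation trees to their leaf literals (one
hot comment per node/branch; `HIERARCHY_FLATTENED` warnings for the
rest), defaulting to key-value style with NHX as an option.  Branch
metadata on a branch with no length has no serializable position and is
dropped with a warning.  eNewick hybrid tags (`label#H1`, `#LGT2`) merge
all same-tag nodes into one network node, re-targeting incoming edges;
the type letter is kept as a `crosslink_type` annotation, a single-use
tag warns `DANGLING_HYBRID`, and writers invert the merge by splitting
multi-parent nodes back into tagged occurrences.

**NEXUS** — a block/command handler registry keyed by (block, command),
replaceable at runtime; unknown blocks and commands are skipped whole
with warnings (DISTANCES, ASSUMPTIONS, NOTES and CHARSTATELABELS land in
this tolerant path).  Supported: TAXA; CHARACTERS/DATA/UNALIGNED with
DATATYPE (including MrBayes `MIXED(a:r1,b:r2)` partitions mapped to
token-set definitions), GAP/MISSING/MATCHCHAR/EQUATE/SYMBOLS/TOKENS and
INTERLEAVE (blocks repeat names and are concatenated per name — a
sequence must not wrap lines without repeating its name); TREES with
TRANSLATE tables; SETS; Mesquite TITLE/LINK; and a custom NETWORKS block
holding eNewick.  DATA implies inline taxon declaration.  Tree node
resolution tries, in order: TRANSLATE entry, taxon label, 1-based taxon
index — applied to terminal nodes always and to internal nodes only on
request, so integer support labels are not mistaken for taxon indices.
An unresolvable terminal label warns and leaves the node unlinked rather
than failing.  `[&R]`/`[&U]` rooting comments become tree-level literal
metadata under the internal rootedness predicate (the same convention the
phyloXML `rooted` attribute maps to).  Internal coordinates are 0-based
half-open everywhere; NEXUS 1-based inclusive ranges (`a-b`, open `a-.`,
stepped `a-b\3`) are converted at the boundary.  The writer emits labels
(not TRANSLATE tables) by default, edits duplicate labels with `_n`
suffixes reported in the translation map, quotes labels containing
punctuation, and adds TITLE/LINK only when several OTU lists force
disambiguation.

**NeXML** — the lossless profile: every `meta` element maps 1:1 to a
literal or resource metadata event, matrices are written sequence-style
by default (`cell` style on option, both read), `states`/`char`
declarations carry token sets and column definitions, and `set` elements
carry the three set kinds.  Anonymous `char` declarations (no label, no
metadata) are emitted by the writer wherever sets or cell-style rows need
column IDs but produce no events on reading — they carry no information.
A literal with an explicit datatype keeps it; one without gets a datatype
inferred from its value only when the value is not a string, so plain
strings round-trip without gaining attributes.

**phyloXML** — predefined elements (taxonomy, sequence, events,
confidence) map bijectively onto internal predicates; `property` tags
carry flat annotations with `applies_to` (node / parent_branch supported;
other values coerce to node with a warning) and XSD datatypes; foreign-
namespace children pass through as XML-content literals.  `clade_relation`
tags add the non-tree edges of networks (on writing, each node's first
incoming edge forms the spanning tree and the rest become relations with
`id_source` references).  Annotations outside the mapped subset follow a
writer strategy: `DROP_NON_REPRESENTABLE` discards whole subtrees,
`FLATTEN_LEAVES_TO_PROPERTIES` (the default) keeps leaf literals as
property tags; both warn per drop.  Outputs are checked structurally (by
re-reading and validating) rather than against the official XML schema
files, which are not vendored.

## Writing through adapters

Direct streaming of the event sequence cannot serve all writers, because
formats demand different element orders.  Writers therefore pull from a
`DocumentAdapter` tree (OTU-list, matrix, tree/network-group adapters)
whose enumeration is repeatable; frequently random-accessed events
(sequence and node starts) are served by ID getters, bulk content by
subsequence writers into `Receiver` objects — receivers count and warn
about anything outside the target capability profile instead of losing it
silently.  `events_to_adapter` buffers a validated stream into list-based
adapters (re-emitting it unchanged — tested as an identity), which is
what powers generic conversion; applications that need true streaming
writes implement the adapter protocol over their own model instead of
buffering.

## The synthetic-document generator

All tests run on generated documents (`FixtureSpec` → `generate_fixture`),
seeded and byte-deterministic.  Defaults model a small study: one OTU
list of five taxa, one 5×20 DNA alignment linked to it, one random binary
tree over the taxa with uniform(0.01, 2.0) branch lengths — sizes chosen
so that a 200-document corpus exercises every content kind in seconds.
Metadata trees mix typed scalars, arrays, booleans, strings and
(at depth ≥ 2) XML fragments, under both predicates and bare string keys;
networks are trees plus one extra cross edge.  The generator emulates
*structure*, not biology: sequences are i.i.d. uniform tokens, trees are
random topologies, annotation values are synthetic.  Passing tests
therefore demonstrate structural fidelity — grammar conformance, lossless
or profile-bounded round trips, warning accounting — on documents far
more densely annotated than typical real files; they do not certify
tolerance of the malformed dialect quirks found in wild files beyond the
dialects explicitly modelled.

## Numerical and degenerate-input choices

Branch lengths parse as IEEE doubles and serialize with `repr`, so
write/read cycles are bit-exact and the dendropy comparison uses exact
equality (well inside the 1e-12 tolerance asserted).  Name shortening
truncates to `max_len − k` and appends a zero-padded counter of width
`k`, with the smallest `k` that resolves all collisions, counters
assigned in input order; names unique under plain truncation are only
truncated.  The scheme is deterministic, injective and idempotent on its
own output; it fails with `CAPACITY_EXCEEDED` when the decimal counter
space is exhausted.  Degenerate inputs are defined rather than rejected:
an empty FASTA stream is an empty document, `" 0 0"` is a valid empty
PHYLIP matrix, `";"` is a single-node tree, an empty NETWORKS block is an
empty group, and a resource annotation with neither href nor children is
legal but flagged `EMPTY_RESOURCE` by the validator (a warning, not an
error).

## Known limitations

PHYLIP interleaved writing, FASTQ, MEGA writing, NEXUS DISTANCES /
ASSUMPTIONS / NOTES blocks, RDF graph export and cross-ontology predicate
translation are out of scope.  A literal annotation carrying *both* a
predicate and a string key keeps only the predicate through NeXML (the
format has one `property` slot).  Sequential PHYLIP rows shorter than the
declared length are consumed as continuations before the mismatch is
reported, so the error may name a later sequence.  The format guesser
cannot identify an empty Newick file (a tree-less document writes zero
bytes), and Newick-vs-relaxed-PHYLIP ambiguity is broken in PHYLIP's
favour when the first line is two integers.
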