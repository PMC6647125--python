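# phylostream

Event-based streaming I/O for phylogenetic file formats.

Phylogenetic workflows juggle a zoo of file formats: classical text
formats (FASTA, PHYLIP, Newick, NEXUS) that dominate in practice but carry
little or no metadata, and modern XML formats (NeXML, phyloXML) with rich,
ontology-aware annotation models.  Tool authors who want to support both
usually end up writing one parser, one writer and one data mapping per
format.  `phylostream` removes that burden: every format is read and
written through a single event-based interface, with no constraints on the
application's own data model.

## The model

A phylogenetic document — OTU (taxon) lists, character matrices and
alignments, trees, networks, element sets, and metadata on any of these —
is linearized into a stream of typed events.  Elements with nested content
become `START`/`END` event pairs; atomic elements are single `SOLE`
events.  The stream obeys a fixed grammar (enforced by
`validate_stream`); cross-references such as *alignment → OTU list* or
*tree node → OTU* are IDs pointing only at events emitted earlier, so a
single forward pass suffices to consume any document.

Metadata is RDF-style: **literal** annotations hold typed values
(scalars, arrays, or nested XML) and **resource** annotations link URIs
and group nested annotations.  Both are identified by an RDF predicate
(`namespace` + `local part`, rendered as a CURIE) and/or a free string
key, which is how the same annotation can surface as a NeXML `meta` tag,
a BEAST-style hot comment `[&support=0.95]`, or a phyloXML `property`
tag.  When a target format cannot hold an annotation, the writer drops or
flattens it and records a coded warning — never a silent loss.

Reading streams events lazily (pull or push mode; memory is O(1) in
document size).  Writing pulls event subsequences from *data adapters*, so
each writer can request the document's parts in the order its format
needs (NEXUS wants taxa before characters; phyloXML only wants trees).

| format  | reads | writes | holds |
|---------|-------|--------|-------|
| FASTA   | yes   | yes    | alignments |
| PHYLIP  | yes (standard + relaxed, interleaved + sequential) | yes (sequential) | alignments |
| Newick / eNewick | yes | yes | trees, networks, hot-comment metadata (NHX + key/value) |
| NEXUS   | yes | yes | OTU lists, matrices, trees, networks, sets, hot-comment metadata |
| NeXML   | yes | yes | everything, losslessly |
| phyloXML| yes | yes | trees, networks, predefined + property metadata |
| MEGA    | yes | —      | alignments, character sets, title/description |

## A worked example

Converting a NEXUS matrix to PHYLIP, whose names are limited to ten
characters:

```python
from phylostream import convert

NEXUS = """#NEXUS
BEGIN TAXA; DIMENSIONS NTAX=3; TAXLABELS A_fine_taxon_name_1
  A_fine_taxon_name_2 short; END;
BEGIN CHARACTERS;
DIMENSIONS NCHAR=6; FORMAT DATATYPE=DNA;
MATRIX
A_fine_taxon_name_1 ACGTAC
A_fine_taxon_name_2 ACGTAA
short               ACGTAG
;
END;
"""
text, result = convert(NEXUS, "phylip")
print(text)
for old, new in result.name_map.pairs:
    if old != new:
        print(f"{old!r} -> {new!r}")
```

prints

```
 3 6
A fine ta1ACGTAC
A fine ta2ACGTAA
short     ACGTAG

'A fine taxon name 1' -> 'A fine ta1'
'A fine taxon name 2' -> 'A fine ta2'
```

The two long names differ only beyond the ten-character cut-off, where
plain truncation (what many tools do) would produce two identical names.
The writer instead truncates to nine characters and appends a counter,
keeping all written names unique, and reports every edit in the returned
old→new translation map so the application can restore the originals.

The same document converted with `convert(NEXUS, "nexml")` round-trips
with zero warnings — NeXML is the lossless profile.  See `examples/` for
more: event listing, metadata in three formats, eNewick networks, and
constant-memory streaming.

## Command line

```bash
phylostream convert in.nex out.xml --to nexml        # any format to any
phylostream events tree.nwk                          # list the event stream
phylostream validate data.fasta                      # grammar check
```

Input formats are guessed from content (`--from` overrides); warnings are
printed to stderr as `WARN <CODE> ...` lines.

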