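"""Pull-parse two small documents and print their event streams.

Every reader linearizes a hierarchical phylogenetic document into the
same typed event stream, so one consumer loop handles every format.
"""

from phylostream import Topology, read_document

FASTA = """>human some description
ACGTAC
>chimp
ACGTAA
"""

NEXUS = """#NEXUS
BEGIN TAXA; DIMENSIONS NTAX=2; TAXLABELS human chimp; END;
BEGIN TREES; TREE t1 = (human:0.1,chimp:0.2); END;
"""

for name, text in [("FASTA", FASTA), ("NEXUS", NEXUS)]:
    print(f"--- {name} (format auto-detected) ---")
    reader = read_document(text, format="auto")
    depth = 0
    for event in reader.events():
        if event.topology is Topology.END:
            depth -= 1
        detail = f" label={event.label!r}" if event.label else ""
        link = f" -> {event.linked_id}" if event.linked_id else ""
        print(f"{'  ' * depth}{event.type.value}.{event.topology.value}"
              f"{detail}{link}")
        if event.topology is Topology.START:
            depth += 1

# Each line is one event; indentation shows element nesting, and the
# "->" arrows are ID references to elements emitted earlier in the
# stream (a NEXUS tree node pointing at its taxon, for example).
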