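"""Convert documents between formats and inspect the loss report.

Conversion composes read -> buffer-into-adapters -> write.  Writing to a
less expressive format never fails silently: the warning log lists every
dropped annotation, and the name translation map records every label the
writer had to edit to satisfy the target format's rules.
"""

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

nexml_text, result = convert(NEXUS, "nexml")
print("--- NEXUS -> NeXML (lossless profile) ---")
print(nexml_text[:400], "...")
print("warnings:", len(result.warnings))

phylip_text, result = convert(NEXUS, "phylip")
print("--- NEXUS -> PHYLIP (names limited to 10 characters) ---")
print(phylip_text)
print("edited labels (old -> new):")
for old, new in result.name_map.pairs:
    if old != new:
        print(f"  {old!r} -> {new!r}")

# The two long names differ only beyond the 10-character cut-off; plain
# truncation would collide, so the writer appends a counter and reports
# the edits so the caller can map the shortened names back.
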