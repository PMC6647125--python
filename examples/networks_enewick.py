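"""Read a phylogenetic network written in Extended Newick.

In eNewick a hybridization node appears several times in the string,
marked by a shared tag such as #H1.  The reader merges all occurrences
into one network node, re-targets the incoming edges, and records the
crosslink type (H = hybridization, LGT = lateral gene transfer,
R = recombination) as metadata.
"""

from phylostream import build_meta_tree, events_to_adapter, read_document

ENEWICK = "((a,(b)#LGT1),(#LGT1,c));"

document = events_to_adapter(read_document(ENEWICK, format="newick").events())
network = document.tree_network_groups[0].members[0]
print("parsed as network:", network.is_network)
print("nodes:", len(network.nodes), " edges:", len(network.edges))

indegree = {}
for edge in network.edges:
    target = edge.start.payload.target_id
    indegree[target] = indegree.get(target, 0) + 1
hybrid = max(indegree, key=indegree.get)
print(f"hybrid node {hybrid} has in-degree {indegree[hybrid]}")
for annotation in build_meta_tree(network.nodes[hybrid].content):
    print(f"  {annotation.effective_key()} = {annotation.value}")

# The two #LGT1 occurrences merged into a single node with two parents;
# its crosslink_type annotation says the extra edge models lateral gene
# transfer.  A tree would have every in-degree at most 1.
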