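"""Canonical tree forms used to compare parsed trees across parsers."""

from __future__ import annotations

from phylostream import EdgeInfo, EventType, TreeOrNetworkAdapter


def canonical_from_adapter(tree: TreeOrNetworkAdapter, digits: int = 12):
    """Order-independent nested form: leaves are (label, length), internal
    nodes are (sorted children tuple, label, length)."""
    children: dict[str, list[tuple[str, float | None]]] = {}
    incoming = set()
    for edge in tree.edges:
        info: EdgeInfo = edge.start.payload
        if info.source_id is None:
            continue
        children.setdefault(info.source_id, []).append(
            (info.target_id, info.length))
        incoming.add(info.target_id)
    roots = [n for n in tree.node_ids() if n not in incoming]
    assert len(roots) == 1

    def canon(node_id: str, length):
        node = tree.nodes[node_id]
        rounded = None if length is None else round(length, digits)
        kids = children.get(node_id, [])
        if not kids:
            return ("leaf", node.start.label, rounded)
        sub = tuple(sorted(canon(c, l) for c, l in kids))
        return ("node", sub, node.start.label, rounded)

    return canon(roots[0], None)


def canonical_from_dendropy(tree, digits: int = 12):
    def canon(node, length):
        rounded = None if length is None else round(length, digits)
        label = node.taxon.label if node.taxon else node.label
        kids = node.child_nodes()
        if not kids:
            return ("leaf", label, rounded)
        sub = tuple(sorted(canon(c, c.edge.length) for c in kids))
        return ("node", sub, label, rounded)

    return canon(tree.seed_node, None)
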