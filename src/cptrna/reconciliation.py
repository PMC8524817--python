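"""Gene-tree / species-tree reconciliation by LCA mapping.

Each gene-tree node v is mapped to M(v), the last common ancestor in the
species tree of the species of v's leaf descendants.  An internal node v
with children u1, u2 is a duplication iff M(u1) = M(v) or M(u2) = M(v);
losses contributed by a child edge (v, ui) are

    max(0, dist(M(v), M(ui)) - 1 + [v is a duplication])

where dist counts species-tree edges.  This yields the parsimony-minimal
duplication and loss counts for the given rooted trees.

Both trees must be rooted and binary; multifurcations are refused (the
resolution choice changes counts) and unrooted gene trees can be rooted by
:func:`root_by_minimal_events`, which exhaustively tries every edge and
keeps the rooting minimizing D + L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

__all__ = [
    "ReconciliationResult",
    "parse_leaf_map",
    "lca_map",
    "reconcile",
    "root_by_minimal_events",
]


class NotBinaryError(ValueError):
    """Tree is unrooted or contains multifurcations; root/resolve first."""


@dataclass
class ReconciliationResult:
    duplications: int
    losses: int
    #: gene-tree internal node -> "duplication" | "speciation"
    node_events: dict = field(default_factory=dict)
    #: (gene node, child index) -> losses along that edge
    edge_losses: dict = field(default_factory=dict)


def parse_leaf_map(gene_tree: dendropy.Tree,
                   mapping: dict[str, str] | None = None) -> dict[str, str]:
    """Gene leaf -> species label; defaults to the ``species|copy`` convention."""
    out = {}
    for leaf in gene_tree.leaf_node_iter():
        label = leaf.taxon.label
        if mapping is not None:
            if label not in mapping:
                raise KeyError(f"gene leaf {label!r} missing from the leaf map")
            out[label] = mapping[label]
        else:
            out[label] = label.split("|")[0]
    return out


def _check_binary(tree: dendropy.Tree, name: str, allow_trifurcating_root: bool = False) -> None:
    for node in tree.preorder_node_iter():
        ch = node.child_nodes()
        if not ch:
            continue
        if node is tree.seed_node and allow_trifurcating_root:
            continue
        if len(ch) != 2:
            raise NotBinaryError(
                f"{name} has a node with {len(ch)} children; root/resolve the "
                "tree first (multifurcations are refused)")


def _species_index(species_tree: dendropy.Tree):
    """Depth and parent tables for constant-ish LCA queries on small trees."""
    depth, parent, by_label = {}, {}, {}
    for node in species_tree.preorder_node_iter():
        parent[node] = node.parent_node
        depth[node] = 0 if node.parent_node is None else depth[node.parent_node] + 1
        if node.is_leaf():
            by_label[node.taxon.label] = node
    return depth, parent, by_label


def _lca(a, b, depth, parent):
    while depth[a] > depth[b]:
        a = parent[a]
    while depth[b] > depth[a]:
        b = parent[b]
    while a is not b:
        a, b = parent[a], parent[b]
    return a


def lca_map(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
            leaf_map: dict[str, str] | None = None) -> dict:
    """Bottom-up LCA mapping M of gene-tree nodes to species-tree nodes."""
    _check_binary(gene_tree, "gene tree")
    _check_binary(species_tree, "species tree")
    depth, parent, by_label = _species_index(species_tree)
    lmap = parse_leaf_map(gene_tree, leaf_map)
    M = {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            sp = lmap[node.taxon.label]
            if sp not in by_label:
                raise KeyError(f"species {sp!r} not in the species tree")
            M[node] = by_label[sp]
        else:
            ch = node.child_nodes()
            m = M[ch[0]]
            for c in ch[1:]:
                m = _lca(m, M[c], depth, parent)
            M[node] = m
    return M


def reconcile(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
              leaf_map: dict[str, str] | None = None) -> ReconciliationResult:
    """Count duplications and losses under the LCA reconciliation."""
    M = lca_map(gene_tree, species_tree, leaf_map)
    depth, parent, _ = _species_index(species_tree)
    D = L = 0
    node_events, edge_losses = {}, {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            continue
        ch = node.child_nodes()
        is_dup = any(M[c] is M[node] for c in ch)
        node_events[node] = "duplication" if is_dup else "speciation"
        if is_dup:
            D += 1
        for k, c in enumerate(ch):
            dist = depth[M[c]] - depth[M[node]]
            losses = max(0, dist - 1 + (1 if is_dup else 0))
            edge_losses[(node, k)] = losses
            L += losses
    return ReconciliationResult(D, L, node_events, edge_losses)


def root_by_minimal_events(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
                           leaf_map: dict[str, str] | None = None) -> tuple[dendropy.Tree, ReconciliationResult]:
    """Root an unrooted gene tree at the edge minimizing D + L.

    Every edge is tried exhaustively; ties go to the rooting whose Newick
    string is lexicographically smallest, for reproducibility.
    """
    best = None
    newick = gene_tree.as_string(schema="newick")
    edges = [e for e in gene_tree.preorder_edge_iter() if e.head_node.parent_node]
    for k in range(len(edges)):
        t = dendropy.Tree.get(data=newick, schema="newick",
                              preserve_underscores=True)
        es = [e for e in t.preorder_edge_iter() if e.head_node.parent_node]
        e = es[k]
        t.reroot_at_edge(e, update_bipartitions=False)
        t.update_bipartitions(suppress_unifurcations=True)
        try:
            _check_binary(t, "gene tree")
        except NotBinaryError:
            continue
        res = reconcile(t, species_tree, leaf_map)
        key = (res.duplications + res.losses,
               t.as_string(schema="newick"))
        if best is None or key < best[0]:
            best = (key, t, res)
    if best is None:
        raise NotBinaryError("no rooting of the gene tree is binary")
    return best[1], best[2]
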