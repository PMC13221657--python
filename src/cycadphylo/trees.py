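"""Small shared tree utilities on top of dendropy.

All pipeline modules treat trees as ``dendropy.Tree`` objects whose taxon
labels are accession ids. Helpers here cover bipartition sets, node ages,
MRCA lookup, pruning, and patristic distances.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import dendropy

from .errors import InputError, TreeValidationError


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def clone(tree: dendropy.Tree) -> dendropy.Tree:
    """Deep copy with an independent taxon namespace, so pruning or
    relabeling the copy can never corrupt the original."""
    out = dendropy.Tree(tree)
    out.migrate_taxon_namespace(dendropy.TaxonNamespace())
    return out


def from_newick(newick: str) -> dendropy.Tree:
    from .phyloio import parse_newick

    return parse_newick(newick)


def leafset_below(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def bipartition_set(tree: dendropy.Tree) -> set[frozenset[frozenset[str]]]:
    """Non-trivial bipartitions as frozensets of the two tip-label sides.

    The representation is self-contained (both sides stored), so bipartitions
    from trees over different leaf sets never collide silently.
    """
    all_leaves = frozenset(leaf_labels(tree))
    bips: set[frozenset[frozenset[str]]] = set()
    for node in tree.preorder_internal_node_iter():
        side = leafset_below(node)
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            bips.add(frozenset({side, other}))
    return bips


def same_topology(a: dendropy.Tree, b: dendropy.Tree) -> bool:
    """Unrooted topological identity by bipartition-set comparison."""
    if frozenset(leaf_labels(a)) != frozenset(leaf_labels(b)):
        return False
    return bipartition_set(a) == bipartition_set(b)


def mrca(tree: dendropy.Tree, labels: Iterable[str]) -> dendropy.Node:
    """Most recent common ancestor of the named tips (ancestor-walk; avoids
    dendropy's cached bipartition bitmasks, which go stale after cloning)."""
    labels = list(labels)
    by_label = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = [lab for lab in labels if lab not in by_label]
    if missing:
        raise InputError(f"tip {missing[0]!r} not in tree")
    if not labels:
        raise InputError("mrca needs at least one tip label")
    node = by_label[labels[0]]
    ancestors = []
    cur = node
    while cur is not None:
        ancestors.append(cur)
        cur = cur.parent_node
    rank = {id(n): i for i, n in enumerate(ancestors)}
    best = 0
    for lab in labels[1:]:
        cur = by_label[lab]
        while id(cur) not in rank:
            cur = cur.parent_node
            if cur is None:
                raise InputError(f"no MRCA found for {labels}")
        best = max(best, rank[id(cur)])
    return ancestors[best]


def node_depths(tree: dendropy.Tree) -> Mapping[dendropy.Node, float]:
    """Distance from the root to every node (edge lengths summed)."""
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def max_tip_depth(tree: dendropy.Tree) -> float:
    depths = node_depths(tree)
    return max(depths[leaf] for leaf in tree.leaf_node_iter())


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> bool:
    depths = node_depths(tree)
    tip_depths = [depths[leaf] for leaf in tree.leaf_node_iter()]
    return max(tip_depths) - min(tip_depths) <= tol


def set_node_ages(tree: dendropy.Tree, tol: float = 1e-6) -> None:
    """Annotate every node with ``.age`` (time before present; tips 0).

    Requires an ultrametric tree; raises TreeValidationError otherwise.
    """
    if not is_ultrametric(tree, tol=tol):
        raise TreeValidationError("tree is not ultrametric; cannot assign ages")
    depths = node_depths(tree)
    height = max(depths[leaf] for leaf in tree.leaf_node_iter())
    for node in tree.preorder_node_iter():
        node.age = height - depths[node]
        if node.is_leaf():
            node.age = 0.0


def prune_tips(tree: dendropy.Tree, labels: Iterable[str]) -> dendropy.Tree:
    """Return a copy of *tree* with the named tips removed.

    Unifurcations created by the removal are suppressed with branch lengths
    summed; a leftover degree-2 root is likewise suppressed.
    """
    labels = set(labels)
    present = set(leaf_labels(tree))
    missing = labels - present
    if missing:
        raise InputError(f"cannot prune absent tips: {sorted(missing)}")
    if len(present - labels) < 2:
        raise InputError("pruning would leave fewer than 2 tips")
    out = clone(tree)
    taxa = [out.taxon_namespace.get_taxon(lab) for lab in sorted(labels)]
    out.prune_taxa(taxa, suppress_unifurcations=True)
    out.purge_taxon_namespace()
    # dendropy can leave a degree-1 root; fold its edge into the child.
    root = out.seed_node
    while len(root.child_nodes()) == 1:
        child = root.child_nodes()[0]
        child.edge.length = (child.edge.length or 0.0) + (root.edge.length or 0.0)
        out.seed_node = child
        child.parent_node = None
        root = child
    return out


def relabel_tips(tree: dendropy.Tree, mapping: Mapping[str, str]) -> None:
    """In-place tip relabeling (labels absent from *mapping* untouched)."""
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label in mapping:
            leaf.taxon.label = mapping[leaf.taxon.label]


def patristic_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """All pairwise tip-to-tip path lengths, keyed by ordered label pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    out: dict[tuple[str, str], float] = {}
    taxa = [leaf.taxon for leaf in tree.leaf_node_iter()]
    for i, ta in enumerate(taxa):
        for tb in taxa[i + 1 :]:
            d = pdm.patristic_distance(ta, tb)
            out[(ta.label, tb.label)] = d
            out[(tb.label, ta.label)] = d
    return out


def total_tree_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.preorder_edge_iter())


def is_binary(tree: dendropy.Tree) -> bool:
    """Fully resolved rooted tree: every internal node has exactly 2 children."""
    return all(
        len(n.child_nodes()) == 2 for n in tree.preorder_internal_node_iter()
    )
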