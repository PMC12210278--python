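"""Tree statistics: bipartition algebra, consensus degree, distances, support.

The consensus degree (CD) between two trees on the same leaf set is the
percentage of identical internal nodes, computed as the shared non-trivial
bipartitions over the L-3 bipartitions of a fully resolved unrooted tree.
With that denominator CD = 100 demands full topological agreement, and for
fully resolved pairs CD relates to the Robinson-Foulds distance as
``cd = 100 * (1 - rf / (2 * (L - 3)))``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .core import LabeledMatrix, PhyloTree, TreeNode
from .errors import InvariantError

__all__ = [
    "Bipartition",
    "CdReport",
    "bipartitions",
    "consensus_degree",
    "rf_distance",
    "ed_matrix",
    "support_summary",
    "monophyly_report",
    "majority_consensus",
    "prune_leaves",
    "root_with_outgroup",
    "midpoint_root",
]


@dataclass(frozen=True)
class Bipartition:
    """A non-trivial split, canonicalized to the side excluding a reference leaf.

    The reference leaf is the lexicographically smallest label of the tree,
    so equal splits compare equal regardless of rooting. ``origin_support``
    is the support of the inducing edge and does not affect identity.
    """

    side: frozenset
    origin_support: float | None = field(default=None, compare=False)


def _clades(tree: PhyloTree) -> list[tuple[frozenset, TreeNode]]:
    """Leaf-label set below each node, postorder."""
    sets: dict[int, frozenset] = {}
    out: list[tuple[frozenset, TreeNode]] = []
    for node in tree.root.postorder():
        if node.is_leaf:
            s = frozenset([node.label])
        else:
            s = frozenset().union(*(sets[id(c)] for c in node.children))
        sets[id(node)] = s
        out.append((s, node))
    return out


def bipartitions(tree: PhyloTree) -> set[Bipartition]:
    """Non-trivial bipartitions induced by the internal edges of a tree.

    Rooting is ignored: the root edge's duplicate split is deduplicated and
    trivial splits (a single leaf vs the rest) are excluded.
    """
    labels = tree.leaf_labels()
    L = len(labels)
    if L < 4:
        raise InvariantError(f"bipartitions need >= 4 leaves, tree has {L}")
    universe = frozenset(labels)
    ref = min(labels)
    by_side: dict[frozenset, float | None] = {}
    for clade, node in _clades(tree):
        if node is tree.root or node.is_leaf:
            continue
        side = universe - clade if ref in clade else clade
        if len(side) < 2 or len(side) > L - 2:
            continue
        if side not in by_side or by_side[side] is None:
            by_side[side] = node.support
    return {Bipartition(side, sup) for side, sup in by_side.items()}


def _require_same_leaves(t1: PhyloTree, t2: PhyloTree) -> int:
    s1, s2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if s1 != s2:
        only1 = sorted(s1 - s2)
        only2 = sorted(s2 - s1)
        raise InvariantError(
            f"leaf sets differ: only in first {only1}; only in second {only2}"
        )
    return len(s1)


@dataclass(frozen=True)
class CdReport:
    tree_a: str
    tree_b: str
    n_shared: int
    denominator: int
    cd: float


def consensus_degree(
    t1: PhyloTree, t2: PhyloTree, name_a: str = "tree_a", name_b: str = "tree_b"
) -> CdReport:
    """Percentage of identical nodes between two trees on one leaf set."""
    L = _require_same_leaves(t1, t2)
    shared = {b.side for b in bipartitions(t1)} & {b.side for b in bipartitions(t2)}
    denom = L - 3
    return CdReport(name_a, name_b, len(shared), denom, 100.0 * len(shared) / denom)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance: size of the bipartition symmetric difference."""
    _require_same_leaves(t1, t2)
    s1 = {b.side for b in bipartitions(t1)}
    s2 = {b.side for b in bipartitions(t2)}
    return len(s1 ^ s2)


def ed_matrix(tree: PhyloTree) -> LabeledMatrix:
    """Patristic (path-length) distances between all leaf pairs."""
    if not tree.has_branch_lengths():
        raise InvariantError("ed_matrix requires branch lengths on every edge")
    leaves = tree.leaves()
    depth: dict[int, float] = {id(tree.root): 0.0}
    for node in tree.root.preorder():
        if node is tree.root:
            continue
        depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)
    ancestors: list[set[int]] = []
    depths = []
    for leaf in leaves:
        anc = set()
        node: TreeNode | None = leaf
        while node is not None:
            anc.add(id(node))
            node = node.parent
        ancestors.append(anc)
        depths.append(depth[id(leaf)])
    n = len(leaves)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            common = ancestors[i] & ancestors[j]
            lca_depth = max(depth[k] for k in common)
            d = depths[i] + depths[j] - 2.0 * lca_depth
            values[i, j] = values[j, i] = d
    return LabeledMatrix(
        [leaf.label for leaf in leaves], values, kind="distance", scale="fraction"
    )


def support_summary(tree: PhyloTree, cutoff: float) -> dict:
    """Count internal nodes with support below a cutoff (percent scale)."""
    if not 0 < cutoff <= 100:
        raise InvariantError("cutoff must be in (0, 100]")
    supports = [
        n.support for n in tree.internal_nodes() if n.support is not None
    ]
    if not supports:
        raise InvariantError("tree has no supported internal nodes")
    n_below = sum(1 for s in supports if s < cutoff)
    return {
        "n_internal": len(supports),
        "n_below": n_below,
        "fraction_below": n_below / len(supports),
    }


def monophyly_report(tree: PhyloTree, mapping: Mapping[str, str]) -> dict[str, dict]:
    """Per-taxon monophyly on the rooted tree as supplied.

    A taxon is monophyletic iff some clade's leaf set equals exactly its leaf
    set; single-leaf taxa are monophyletic by convention. Also reports the
    size of the smallest clade containing all of the taxon's leaves.
    """
    leaf_labels = tree.leaf_labels()
    unmapped = [lab for lab in leaf_labels if lab not in mapping]
    if unmapped:
        raise InvariantError(f"unmapped leaves: {sorted(unmapped)}")
    taxa: dict[str, set] = {}
    for lab in leaf_labels:
        taxa.setdefault(mapping[lab], set()).add(lab)
    clade_sets = [clade for clade, _node in _clades(tree)]
    clade_lookup = set(clade_sets)
    report: dict[str, dict] = {}
    for taxon, members in sorted(taxa.items()):
        fs = frozenset(members)
        containing = min(len(c) for c in clade_sets if c >= fs)
        report[taxon] = {
            "monophyletic": fs in clade_lookup,
            "n_leaves": len(members),
            "smallest_containing_clade": containing,
        }
    return report


def prune_leaves(tree: PhyloTree, labels: Iterable[str]) -> PhyloTree:
    """Remove the named leaves; unary nodes left behind are suppressed."""
    drop = set(labels)
    missing = drop - set(tree.leaf_labels())
    if missing:
        raise InvariantError(f"cannot prune absent leaves {sorted(missing)}")
    if len(drop) >= tree.n_leaves - 1:
        raise InvariantError("pruning would leave fewer than two leaves")
    t = tree.copy()
    for leaf in list(t.leaves()):
        if leaf.label in drop:
            parent = leaf.parent
            assert parent is not None
            parent.children.remove(leaf)
    return PhyloTree(t.root, normalize=True)


def root_with_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Reroot on the edge above the named leaf, splitting its branch length.

    Edge supports travel with their edges: after rerooting, the support of a
    flipped edge is carried by its new child node.
    """
    if outgroup not in tree.leaf_labels():
        raise InvariantError(f"outgroup {outgroup!r} is not a leaf of the tree")
    t = tree.copy()
    leaf = next(n for n in t.leaves() if n.label == outgroup)
    parent = leaf.parent
    if parent is None:
        raise InvariantError("cannot root a single-leaf tree")
    if parent is t.root and len(parent.children) == 2:
        return t  # already rooted on that edge

    def rehang(node: TreeNode, from_child: TreeNode | None,
               edge_len: float | None, edge_support: float | None) -> TreeNode:
        new = TreeNode(node.label, edge_len, edge_support)
        for c in node.children:
            if c is not from_child:
                new.add_child(c)
                c.parent = new
        if node.parent is not None:
            new.add_child(rehang(node.parent, node, node.length, node.support))
        return new

    half = None if leaf.length is None else leaf.length / 2.0
    new_root = TreeNode()
    out_leaf = TreeNode(label=leaf.label, length=half)
    new_root.add_child(out_leaf)
    new_root.add_child(rehang(parent, leaf, half, None))
    return PhyloTree(new_root, normalize=True)


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    The midpoint lies on some edge of the diameter path; that edge is split
    by a new root node, and the far side of the tree is re-hung from it.
    """
    if not tree.has_branch_lengths():
        raise InvariantError("midpoint rooting requires branch lengths")
    dm = ed_matrix(tree)
    values = dm.values
    i, j = np.unravel_index(int(np.argmax(values)), values.shape)
    a, b = dm.labels[int(i)], dm.labels[int(j)]
    target = values[i, j] / 2.0
    # reroot at one end of the diameter so the whole path runs leafward to b
    t = root_with_outgroup(tree, a)
    leaf_b = next(n for n in t.leaves() if n.label == b)
    node: TreeNode = leaf_b
    walked = 0.0
    while node.parent is not None and walked + (node.length or 0.0) < target - 1e-12:
        walked += node.length or 0.0
        node = node.parent
    parent = node.parent
    if parent is None:
        return t
    remain = target - walked  # distance from node up to the midpoint
    parent.children.remove(node)
    upper_len = (node.length or 0.0) - remain
    node.length = remain
    node.parent = None

    def rehang(nd: TreeNode, from_child: TreeNode | None,
               edge_len: float | None, edge_support: float | None) -> TreeNode:
        new = TreeNode(nd.label, edge_len, edge_support)
        for c in nd.children:
            if c is not from_child:
                new.add_child(c)
                c.parent = new
        if nd.parent is not None:
            new.add_child(rehang(nd.parent, nd, nd.length, nd.support))
        return new

    new_root = TreeNode()
    new_root.add_child(node)
    new_root.add_child(rehang(parent, None, max(upper_len, 0.0), None))
    return PhyloTree(new_root, normalize=True)


def majority_consensus(trees: Iterable[PhyloTree], threshold: float = 0.5) -> PhyloTree:
    """Majority-rule consensus containing exactly the majority bipartitions.

    A bipartition is retained iff it occurs in strictly more than
    ``threshold`` of the input trees; no greedy addition of further
    compatible splits is performed. Each retained internal node carries its
    occurrence count in ``node.recovery``.
    """
    trees = list(trees)
    if len(trees) < 2:
        raise InvariantError("consensus needs at least two trees")
    first = trees[0]
    for other in trees[1:]:
        _require_same_leaves(first, other)
    labels = sorted(first.leaf_labels())
    universe = frozenset(labels)
    ref = min(labels)
    counts: Counter = Counter()
    for t in trees:
        for b in bipartitions(t):
            counts[b.side] += 1
    retained = {
        side: c for side, c in counts.items() if c > threshold * len(trees)
    }
    # orient every retained split as the clade not containing the reference
    # leaf and nest clades by containment (majority splits are compatible
    # for threshold >= 0.5; anything incompatible is a hard error).
    clades = sorted(retained, key=len, reverse=True)
    root = TreeNode()
    root.recovery = len(trees)
    node_sets: list[tuple[frozenset, TreeNode]] = [(universe, root)]
    for side in clades:
        host_set, host = node_sets[0]
        for cs, node in node_sets[1:]:
            if side <= cs and len(cs) < len(host_set):
                host_set, host = cs, node
            elif side & cs and not (side <= cs or cs <= side or side >= cs):
                raise InvariantError(
                    "incompatible majority bipartitions (threshold below 0.5?)"
                )
        new = TreeNode()
        new.recovery = retained[side]
        # adopt any existing children of the host that lie inside the new clade
        for cs, node in list(node_sets):
            if node.parent is host and cs < side:
                host.children.remove(node)
                new.add_child(node)
        host.add_child(new)
        node_sets.append((side, new))
    for lab in labels:
        best_set, best_node = universe, root
        for cs, node in node_sets[1:]:
            if lab in cs and len(cs) < len(best_set):
                best_set, best_node = cs, node
        best_node.add_child(TreeNode(label=lab))
    return PhyloTree(root, normalize=False)
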