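"""Phylogenetic tree manipulation: rooting, pruning, collapsing, distances.

Trees are rooted, with branch lengths stored on the child node of each edge
and internal-node labels interpreted as numeric support values when they
parse as numbers, or as node names otherwise.
"""

from __future__ import annotations

import copy as _copy
import sys
from io import StringIO
from itertools import combinations


class TreeError(ValueError):
    """Raised for invalid tree operations (unknown OTU, too few leaves...)."""


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


class TreeNode:
    """One node of a rooted tree.

    ``length`` is the length of the edge to the parent (0.0 at the root).
    ``label`` is the leaf name for tips; for internal nodes it is either a
    numeric support value or a node name.
    """

    __slots__ = ("children", "parent", "length", "label", "has_length")

    def __init__(self, label=None, length=0.0, has_length=False):
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.label = label
        self.length = length
        self.has_length = has_length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def support(self) -> float | None:
        """Numeric support value, if this internal node carries one."""
        if self.is_leaf or self.label is None:
            return None
        return float(self.label) if _is_number(self.label) else None

    @property
    def name(self) -> str | None:
        if self.label is None:
            return None
        if not self.is_leaf and _is_number(self.label):
            return None
        return self.label

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {self.label!r} {kind} len={self.length}>"


class PhyloTree:
    """A rooted phylogenetic tree."""

    def __init__(self, root: TreeNode):
        self.root = root

    def nodes(self):
        """All nodes, preorder."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def find_leaf(self, name: str) -> TreeNode | None:
        for leaf in self.leaves():
            if leaf.label == name:
                return leaf
        return None

    def copy(self) -> "PhyloTree":
        return _copy.deepcopy(self)

    def __eq__(self, other):
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return _node_eq(self.root, other.root)

    def __repr__(self):  # pragma: no cover
        return f"<PhyloTree with {len(self.leaves())} leaves>"


def _node_eq(a: TreeNode, b: TreeNode) -> bool:
    if a.label != b.label or abs(a.length - b.length) > 1e-12:
        return False
    if len(a.children) != len(b.children):
        return False
    return all(_node_eq(x, y) for x, y in zip(a.children, b.children))


# ---------------------------------------------------------------------------
# statistics


def total_length(tree: PhyloTree) -> float:
    """Sum of all branch lengths."""
    return sum(n.length for n in tree.nodes())


def _node_depths(tree: PhyloTree) -> dict:
    depths = {tree.root: tree.root.length}
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for child in node.children:
            depths[child] = depths[node] + child.length
            stack.append(child)
    return depths


def otu_depths(tree: PhyloTree) -> list[tuple[str, float]]:
    """Root-to-leaf path length for every OTU, in leaf order."""
    depths = _node_depths(tree)
    return [(leaf.label, depths[leaf]) for leaf in tree.leaves()]


def _lca(a: TreeNode, b: TreeNode) -> TreeNode:
    seen = set()
    node = a
    while node is not None:
        seen.add(id(node))
        node = node.parent
    node = b
    while node is not None:
        if id(node) in seen:
            return node
        node = node.parent
    raise TreeError("nodes share no common ancestor (disconnected tree)")


def leaf_distance(tree: PhyloTree, a: TreeNode, b: TreeNode,
                  depths: dict | None = None) -> float:
    if depths is None:
        depths = _node_depths(tree)
    anc = _lca(a, b)
    return depths[a] + depths[b] - 2.0 * depths[anc]


def pairwise_distances(tree: PhyloTree) -> tuple[list[str], list[list[float]]]:
    """Patristic distance matrix over leaves, in leaf order."""
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise TreeError("pairwise distances need at least 2 leaves")
    depths = _node_depths(tree)
    n = len(leaves)
    mat = [[0.0] * n for _ in range(n)]
    for i, j in combinations(range(n), 2):
        d = leaf_distance(tree, leaves[i], leaves[j], depths)
        mat[i][j] = mat[j][i] = d
    return [l.label for l in leaves], mat


def distance_map(tree: PhyloTree) -> dict[frozenset, float]:
    """Patristic distances keyed by unordered leaf-name pair."""
    names, mat = pairwise_distances(tree)
    return {
        frozenset((names[i], names[j])): mat[i][j]
        for i, j in combinations(range(len(names)), 2)
    }


# ---------------------------------------------------------------------------
# rerooting


def _root_path(node: TreeNode) -> list[TreeNode]:
    chain = []
    while node is not None:
        chain.append(node)
        node = node.parent
    return chain


def _reroot_at_node(tree: PhyloTree, node: TreeNode) -> None:
    """Make ``node`` the root, reversing parent links along its root path.

    Support labels ride on edges (stored at the child end), so when an edge
    is reversed its numeric label moves to the new child end. Non-numeric
    internal names stay with their node.
    """
    if node is tree.root:
        return
    chain = _root_path(node)  # node ... old root
    supports = [
        c.label if (c.label is not None and not c.is_leaf and _is_number(c.label))
        else None
        for c in chain
    ]
    lengths = [c.length for c in chain]
    for i in range(len(chain) - 1):
        chain[i + 1].children.remove(chain[i])
    for i in range(len(chain) - 1):
        child, par = chain[i], chain[i + 1]
        child.children.append(par)
        par.parent = child
        par.length = lengths[i]
        par.has_length = chain[i].has_length
        # shift the edge's support label to its new child end
        if supports[i] is not None or (par.label is not None and _is_number(par.label)):
            par.label = supports[i]
    node.parent = None
    node.length = 0.0
    node.has_length = False
    if supports[0] is not None:
        node.label = None
    # splice an old binary root that became a unifurcation
    old_root = chain[-1]
    if len(old_root.children) == 1:
        lone = old_root.children[0]
        lone.length += old_root.length
        lone.parent = old_root.parent
        old_root.parent.children[old_root.parent.children.index(old_root)] = lone
    tree.root = node


def _reroot_at_edge(tree: PhyloTree, child: TreeNode, dist_from_child: float,
                    tol: float = 1e-9) -> None:
    """Place the root on the edge above ``child``, ``dist_from_child`` away."""
    if dist_from_child <= tol:
        _reroot_at_node(tree, child)
        return
    if dist_from_child >= child.length - tol:
        _reroot_at_node(tree, child.parent)
        return
    parent = child.parent
    mid = TreeNode(length=child.length - dist_from_child, has_length=True)
    parent.children[parent.children.index(child)] = mid
    mid.parent = parent
    mid.add_child(child)
    child.length = dist_from_child
    _reroot_at_node(tree, mid)


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties for the diameter pair are broken by lexicographic leaf-name order
    so output is deterministic. Total length and all patristic distances are
    preserved.
    """
    out = tree.copy()
    leaves = out.leaves()
    if len(leaves) < 2:
        raise TreeError("midpoint rooting needs at least 2 leaves")
    depths = _node_depths(out)
    best = None
    for a, b in combinations(leaves, 2):
        d = leaf_distance(out, a, b, depths)
        key = (-d, tuple(sorted((a.label, b.label))))
        if best is None or key < best[0]:
            best = (key, a, b, d)
    _, a, b, diameter = best
    if diameter <= 0:
        raise TreeError("midpoint undefined: all pairwise distances are zero")
    half = diameter / 2.0
    anc = _lca(a, b)
    up = []  # edges walked child->parent, from a to the LCA
    node = a
    while node is not anc:
        up.append(node)
        node = node.parent
    down = []  # edges walked parent->child, from the LCA to b
    node = b
    while node is not anc:
        down.append(node)
        node = node.parent
    down.reverse()
    cum = 0.0
    for child in up:
        if cum + child.length >= half - 1e-12:
            _reroot_at_edge(out, child, half - cum)
            return out
        cum += child.length
    for child in down:
        if cum + child.length >= half - 1e-12:
            _reroot_at_edge(out, child, child.length - (half - cum))
            return out
        cum += child.length
    raise AssertionError("midpoint beyond path end")  # pragma: no cover


def reroot_outgroup(tree: PhyloTree, otu: str) -> PhyloTree:
    """Insert a new root at the midpoint of the outgroup's pendant edge."""
    out = tree.copy()
    leaf = out.find_leaf(otu)
    if leaf is None:
        raise TreeError(f"unknown OTU: {otu!r}")
    if leaf is out.root:
        raise TreeError("cannot reroot a single-leaf tree")
    if leaf.length > 0:
        _reroot_at_edge(out, leaf, leaf.length / 2.0)
    else:
        _reroot_at_node(out, leaf.parent)
    return out


# ---------------------------------------------------------------------------
# pruning


def _strip(node: TreeNode, drop: set) -> TreeNode | None:
    """Remove leaves in ``drop``; splice unifurcations, summing edge lengths."""
    if node.is_leaf:
        return None if id(node) in drop else node
    kept = []
    for child in node.children:
        sub = _strip(child, drop)
        if sub is not None:
            sub.parent = node
            kept.append(sub)
    node.children = kept
    if not kept:
        return None
    if len(kept) == 1:
        lone = kept[0]
        lone.length += node.length
        lone.parent = node.parent
        return lone
    return node


def delete_otus(tree: PhyloTree, otus: list[str]) -> PhyloTree:
    """Remove the named leaves; distances among survivors are unchanged."""
    out = tree.copy()
    names = set(out.leaf_names())
    missing = [o for o in otus if o not in names]
    if missing:
        raise TreeError("unknown OTU(s): " + ", ".join(missing))
    if len(names) - len(set(otus)) < 2:
        raise TreeError("deletion would leave fewer than 2 leaves")
    drop = {id(l) for l in out.leaves() if l.label in set(otus)}
    root = _strip(out.root, drop)
    root.parent = None
    root.length = 0.0
    root.has_length = False
    out.root = root
    return out


def subset(tree: PhyloTree, targets: list[str]) -> PhyloTree:
    """Minimal subtree spanning the target OTUs (rooted at their LCA), or
    the intact clade below a named internal node when a single non-OTU
    target is given."""
    leaf_names = set(tree.leaf_names())
    if len(targets) == 1 and targets[0] not in leaf_names:
        name = targets[0]
        for node in tree.nodes():
            if not node.is_leaf and node.name == name:
                clade = _copy.deepcopy(node)
                clade.parent = None
                clade.length = 0.0
                clade.has_length = False
                return PhyloTree(clade)
        raise TreeError(f"unknown OTU or internal node: {name!r}")
    missing = [t for t in targets if t not in leaf_names]
    if missing:
        raise TreeError("unknown OTU(s): " + ", ".join(missing))
    if len(targets) == 1:
        # an OTU and an internal node may share a name; the OTU wins
        print(f"subset: interpreting {targets[0]!r} as an OTU", file=sys.stderr)
    out = tree.copy()
    keep = set(targets)
    drop = {id(l) for l in out.leaves() if l.label not in keep}
    root = _strip(out.root, drop)
    root.parent = None
    root.length = 0.0
    root.has_length = False
    out.root = root
    return out


def collapse_low_support(tree: PhyloTree, threshold: float) -> PhyloTree:
    """Contract every internal edge whose support is below ``threshold``.

    The contracted edge's length is added to each promoted child's edge so
    root-to-leaf depths are preserved. Unlabeled internal nodes are never
    collapsed (a warning is emitted on the diagnostic stream).
    """
    out = tree.copy()
    unlabeled = False
    # post-order so nested weak edges collapse in one pass
    order = []
    stack = [out.root]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(node.children)
    for node in reversed(order):
        if node.is_leaf or node is out.root:
            continue
        if node.label is None:
            unlabeled = True
            continue
        support = node.support
        if support is None:
            continue
        if support < threshold:
            parent = node.parent
            idx = parent.children.index(node)
            for child in node.children:
                child.length += node.length
                child.parent = parent
            parent.children[idx:idx + 1] = node.children
    if unlabeled:
        print("collapse: unlabeled internal node(s) left intact",
              file=sys.stderr)
    return out


# ---------------------------------------------------------------------------
# rendering


def ascii_render(tree: PhyloTree) -> str:
    """Monospace cladogram; deterministic, one line per leaf (at least)."""
    from Bio import Phylo

    from .io_formats import write_tree

    buf = StringIO()
    phylo_tree = Phylo.read(StringIO(write_tree(tree)), "newick")
    Phylo.draw_ascii(phylo_tree, file=buf)
    return buf.getvalue()
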