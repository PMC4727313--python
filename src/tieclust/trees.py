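"""Dendrogram data model, Newick I/O and canonical forms.

A dendrogram is a rooted, strictly binary, leaf-labeled tree: the output of
an agglomerative hierarchical clustering run.  Every internal node (the root
included) defines a *nontrivial subtree* -- a branch with at least two
leaves.  Two derived families drive the cluster-contrast functions:

* the subtree partition ``P(D)``: the set of all nontrivial subtrees of
  ``D``, here represented by their canonical keys;
* the leaf-set family ``N(D)``: the leaf sets of those subtrees.

Both families have exactly ``n - 1`` members for a tree with ``n`` leaves.

Canonical form: children are ordered by the lexicographically smallest leaf
label of their subtree, and the canonical key of a node is built from its
children's keys in that order.  Two trees have equal keys iff they are
isomorphic as rooted, unordered, leaf-labeled trees, so key equality decides
"is this cluster a branch of that dendrogram".
"""

from __future__ import annotations

import io
from typing import Iterator, Optional

import dendropy

__all__ = [
    "Node",
    "Dendrogram",
    "parse_newick",
    "write_newick",
    "canonical_key",
    "subtree_partition",
    "leafset_family",
]


class Node:
    """Immutable node of a binary leaf-labeled tree.

    Build leaves with :meth:`leaf` and internal nodes with :meth:`join`;
    canonical key, leaf set and minimum leaf label are computed once at
    construction.  ``height`` is the dissimilarity at which the node's two
    children were merged (``None`` for leaves and for parsed trees, whose
    branch lengths are ignored).
    """

    __slots__ = ("label", "children", "height", "key", "leaves", "min_leaf")

    def __init__(self, label, children, height, key, leaves, min_leaf):
        self.label = label
        self.children = children
        self.height = height
        self.key = key
        self.leaves = leaves
        self.min_leaf = min_leaf

    @classmethod
    def leaf(cls, label: str) -> "Node":
        if not label:
            raise ValueError("leaf label must be a non-empty string")
        return cls(label, (), None, label, frozenset([label]), label)

    @classmethod
    def join(cls, a: "Node", b: "Node", height: Optional[float] = None) -> "Node":
        if a.leaves & b.leaves:
            raise ValueError(
                f"children share leaves: {sorted(a.leaves & b.leaves)}"
            )
        # canonical child order: smallest leaf label first
        if b.min_leaf < a.min_leaf:
            a, b = b, a
        key = f"({a.key},{b.key})"
        return cls(None, (a, b), height, key, a.leaves | b.leaves, a.min_leaf)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        """Depth-first iteration over all nodes of the subtree."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.key!r})"


class Dendrogram:
    """Rooted strictly binary leaf-labeled tree.

    Wraps a :class:`Node` root and provides the derived families used by the
    contrast functions.  Equality and hashing go through the canonical key.
    """

    __slots__ = ("root",)

    def __init__(self, root: Node):
        if root.is_leaf:
            raise ValueError("a dendrogram needs at least 2 leaves")
        if len(root.leaves) < 2:
            raise ValueError("a dendrogram needs at least 2 leaves")
        self.root = root

    # -- basic structure ---------------------------------------------------

    @property
    def leaves(self) -> frozenset:
        return self.root.leaves

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves)

    @property
    def canonical_key(self) -> str:
        return self.root.key

    def internal_nodes(self) -> Iterator[Node]:
        for node in self.root.walk():
            if not node.is_leaf:
                yield node

    # -- derived families --------------------------------------------------

    def subtree_partition(self) -> frozenset:
        """Canonical keys of all nontrivial subtrees (one per internal node).

        The root counts; singletons do not.  Cardinality is ``n - 1``.
        """
        return frozenset(node.key for node in self.internal_nodes())

    def leafset_family(self) -> frozenset:
        """Leaf sets of all nontrivial subtrees; cardinality ``n - 1``."""
        return frozenset(node.leaves for node in self.internal_nodes())

    def subtree_partitions_by_node(self):
        """For each internal node g, the partition P(g) as a set of keys.

        Returned as a list of frozensets, one per internal node of the tree
        (root included).  Used by the relaxed-graph contrast, which maximizes
        a Jaccard index over these partitions.
        """
        out = {}

        def collect(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset()
            part = frozenset([node.key]).union(
                *(collect(c) for c in node.children)
            )
            out[id(node)] = part
            return part

        collect(self.root)
        return list(out.values())

    def cherries(self) -> frozenset:
        """Leaf-pair subtrees, as frozensets of two labels."""
        return frozenset(
            node.leaves
            for node in self.internal_nodes()
            if len(node.leaves) == 2
        )

    # -- serialization -----------------------------------------------------

    def newick(self, with_heights: bool = False) -> str:
        return write_newick(self, with_heights=with_heights)

    # -- dunder ------------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dendrogram):
            return NotImplemented
        return self.root.key == other.root.key

    def __hash__(self) -> int:
        return hash(self.root.key)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Dendrogram({self.newick()!r})"


def parse_newick(text: str) -> Dendrogram:
    """Parse a single Newick string into a :class:`Dendrogram`.

    Branch lengths and internal node labels are accepted and ignored: the
    contrast functions depend only on topology.  Non-binary nodes and
    duplicate leaf labels are rejected.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        kids = dnode.child_nodes()
        if not kids:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            if not label:
                raise ValueError("leaf without a label in Newick input")
            return Node.leaf(str(label))
        if len(kids) == 1:
            # unifurcation (e.g. "(a);" or a knee node): collapse through it
            return convert(kids[0])
        if len(kids) != 2:
            raise ValueError(
                f"non-binary node with {len(kids)} children: "
                "multifurcating dendrograms are not supported"
            )
        return Node.join(convert(kids[0]), convert(kids[1]))

    root = convert(tree.seed_node)
    if root.is_leaf:
        raise ValueError("a dendrogram needs at least 2 leaves")
    n_leaf_nodes = sum(1 for nd in root.walk() if nd.is_leaf)
    if n_leaf_nodes != len(root.leaves):
        raise ValueError("duplicate leaf labels in Newick input")
    return Dendrogram(root)


def _write(node: Node, with_heights: bool, parent_height) -> str:
    if node.is_leaf:
        s = node.label
    else:
        inner = ",".join(
            _write(c, with_heights, node.height) for c in node.children
        )
        s = f"({inner})"
    if with_heights and parent_height is not None:
        child_height = node.height if node.height is not None else 0.0
        s += f":{parent_height - child_height:g}"
    return s


def write_newick(tree: Dendrogram, with_heights: bool = False) -> str:
    """Serialize a dendrogram in canonical child order.

    With ``with_heights`` set, branch lengths are emitted as differences of
    merge heights (leaves sit at height 0); every internal node must then
    carry a height.
    """
    if with_heights:
        missing = [n for n in tree.internal_nodes() if n.height is None]
        if missing:
            raise ValueError("with_heights requires merge heights on all nodes")
    return _write(tree.root, with_heights, None) + ";"


def canonical_key(tree: Dendrogram) -> str:
    """Opaque key; equal for two trees iff they are isomorphic as rooted,
    unordered, leaf-labeled trees."""
    return tree.canonical_key


def subtree_partition(tree: Dendrogram) -> frozenset:
    """The family P(D): canonical keys of D's nontrivial subtrees."""
    return tree.subtree_partition()


def leafset_family(tree: Dendrogram) -> frozenset:
    """The family N(D): leaf sets of D's nontrivial subtrees."""
    return tree.leafset_family()
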