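"""Rooted phylogenetic trees with integer-percent bootstrap supports.

This module is the substrate for every downstream stage: newick I/O
(parsing delegated to :mod:`dendropy`), bipartition algebra, outgroup
rooting, and support-threshold edge collapsing.

Conventions
-----------
* Supports are integer percents in ``[0, 100]`` attached to internal
  non-root edges (stored on the child node of the edge), following the
  common RAxML convention of supports as internal node labels.  Newick
  files whose numeric internal labels all lie in ``[0, 1]`` are
  interpreted as fractions and rescaled to percent (logged).
* Child order is never semantically meaningful; :meth:`PhyloTree.canonicalize`
  sorts children by smallest descendant leaf label so that traversals and
  serializations are deterministic.
* An edge with no support value is *never* collapsed by
  :func:`collapse_low_support` but counts as support 0 wherever a support
  threshold is applied to it (conservative in both directions).
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Iterator, Optional

import dendropy

logger = logging.getLogger("hotrecon")

__all__ = [
    "TreeError",
    "NewickParseError",
    "Node",
    "PhyloTree",
    "Bipartition",
    "parse_newick",
    "serialize_newick",
    "bipartition_set",
    "are_compatible",
    "root_with_outgroup",
    "collapse_low_support",
    "prune_to_taxa",
]


class TreeError(ValueError):
    """Invalid tree structure or invalid operation on a tree."""


class NewickParseError(TreeError):
    """Malformed newick input."""


_NUMERIC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


class Node:
    """One node of a rooted tree.

    ``support`` is the integer-percent support of the edge *above* this
    node (``None`` for leaves, the root, and unsupported edges).
    """

    __slots__ = ("label", "children", "parent", "length", "support")

    def __init__(
        self,
        label: Optional[str] = None,
        children: Optional[list["Node"]] = None,
        length: Optional[float] = None,
        support: Optional[int] = None,
    ) -> None:
        self.label = label
        self.children: list[Node] = children if children is not None else []
        self.parent: Optional[Node] = None
        self.length = length
        self.support = support
        for c in self.children:
            c.parent = self

    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf() else f"internal({len(self.children)})"
        return f"<Node {kind} label={self.label!r} support={self.support!r}>"


class PhyloTree:
    """A rooted tree with uniquely labeled leaves.

    Invariants enforced at construction: leaf labels are unique and
    nonempty; internal nodes have at least two children; the root carries
    no support value (supports belong to edges, and the root has none).
    """

    def __init__(self, root: Node) -> None:
        self.root = root
        self._validate()

    # ------------------------------------------------------------------
    # structure & traversal
    # ------------------------------------------------------------------
    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.postorder():
            if node.is_leaf():
                if not node.label:
                    raise TreeError("leaf with empty label")
                if node.label in seen:
                    raise TreeError(f"duplicate leaf label: {node.label!r}")
                seen.add(node.label)
            elif len(node.children) < 2:
                raise TreeError("internal node with fewer than 2 children")
            if node.support is not None and not (0 <= node.support <= 100):
                raise TreeError(f"support {node.support} outside [0, 100]")
        if self.root.support is not None:
            raise TreeError("root node must not carry a support value")

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for c in reversed(node.children):
                stack.append(c)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf()]

    @property
    def leaf_labels(self) -> frozenset:
        return frozenset(n.label for n in self.leaves())

    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    def clades(self) -> dict[Node, frozenset]:
        """Leaf-label set of the subtree rooted at each node."""
        out: dict[Node, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf():
                out[node] = frozenset((node.label,))
            else:
                out[node] = frozenset().union(*(out[c] for c in node.children))
        return out

    def copy(self) -> "PhyloTree":
        def rec(node: Node) -> Node:
            new = Node(node.label, [rec(c) for c in node.children], node.length, node.support)
            return new

        return PhyloTree(rec(self.root))

    def canonicalize(self) -> "PhyloTree":
        """Sort children in place by smallest descendant leaf label; return self."""
        mins: dict[Node, str] = {}
        for node in self.postorder():
            if node.is_leaf():
                mins[node] = node.label
            else:
                node.children.sort(key=lambda c: mins[c])
                mins[node] = mins[node.children[0]]
        return self

    def isomorphic(self, other: "PhyloTree", check_support: bool = True) -> bool:
        """Topological identity as rooted trees (and, optionally, supports)."""

        def shape(tree: PhyloTree) -> tuple:
            memo: dict[Node, tuple] = {}
            for node in tree.postorder():
                if node.is_leaf():
                    memo[node] = ("leaf", node.label)
                else:
                    kids = tuple(sorted(memo[c] for c in node.children))
                    sup = tuple(
                        sorted(
                            (memo[c], c.support if check_support else None)
                            for c in node.children
                        )
                    )
                    memo[node] = ("int", sup if check_support else kids)
            return memo[tree.root]

        return shape(self) == shape(other)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {self.n_leaves()} leaves>"


# ----------------------------------------------------------------------
# Bipartitions
# ----------------------------------------------------------------------
class Bipartition:
    """An unordered split of a taxon set into two disjoint nonempty sides.

    The side containing the lexicographically smallest taxon is stored
    first, which makes equality, hashing and ordering well defined.
    """

    __slots__ = ("side1", "side2")

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]) -> None:
        a, b = frozenset(side_a), frozenset(side_b)
        if not a or not b:
            raise TreeError("bipartition sides must be nonempty")
        if a & b:
            raise TreeError("bipartition sides must be disjoint")
        if min(a) <= min(b):
            self.side1, self.side2 = a, b
        else:
            self.side1, self.side2 = b, a

    @property
    def taxa(self) -> frozenset:
        return self.side1 | self.side2

    @property
    def smaller_side(self) -> frozenset:
        if len(self.side1) != len(self.side2):
            return min(self.side1, self.side2, key=len)
        return self.side1

    def is_trivial(self) -> bool:
        return min(len(self.side1), len(self.side2)) == 1

    def _key(self) -> tuple:
        return (tuple(sorted(self.side1)), tuple(sorted(self.side2)))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Bipartition) and self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def __lt__(self, other: "Bipartition") -> bool:
        return self._key() < other._key()

    def __repr__(self) -> str:
        fmt = lambda s: ",".join(sorted(s))
        return f"{fmt(self.side1)}|{fmt(self.side2)}"


def are_compatible(b1: Bipartition, b2: Bipartition) -> bool:
    """Two splits of the same taxon set can coexist in one tree iff at
    least one of the four pairwise side-intersections is empty."""
    if b1.taxa != b2.taxa:
        raise TreeError("bipartitions are on different taxon sets")
    return (
        not (b1.side1 & b2.side1)
        or not (b1.side1 & b2.side2)
        or not (b1.side2 & b2.side1)
        or not (b1.side2 & b2.side2)
    )


def bipartition_set(tree: PhyloTree) -> list[tuple[Bipartition, Optional[int]]]:
    """Non-trivial bipartitions induced by internal non-root edges.

    Returns ``(bipartition, support)`` pairs in canonical (sorted) order;
    ``support`` is ``None`` for edges without a value.  The two edges
    adjacent to the root of a rooted tree induce the same unrooted split;
    it is reported once (with the larger of the two supports if both
    carry one).
    """
    all_taxa = tree.leaf_labels
    clades = tree.clades()
    found: dict[Bipartition, Optional[int]] = {}
    for node in tree.postorder():
        if node is tree.root or node.is_leaf():
            continue
        clade = clades[node]
        rest = all_taxa - clade
        if not rest:
            continue
        bp = Bipartition(clade, rest)
        if bp.is_trivial():
            continue
        sup = node.support
        if bp in found:
            prev = found[bp]
            if prev is None or (sup is not None and sup > prev):
                found[bp] = sup
        else:
            found[bp] = sup
    return sorted(found.items(), key=lambda kv: kv[0]._key())


# ----------------------------------------------------------------------
# Newick I/O
# ----------------------------------------------------------------------
def _coerce_support(raw: str) -> Optional[float]:
    if raw is None or not _NUMERIC_RE.match(raw.strip()):
        return None
    return float(raw)


def parse_newick(text: str, support_scale: str = "auto") -> PhyloTree:
    """Parse a newick string into a :class:`PhyloTree`.

    Numeric internal-node labels are read as supports.  ``support_scale``
    controls their interpretation: ``"percent"`` (use as-is),
    ``"fraction"`` (multiply by 100), or ``"auto"`` (rescale iff every
    numeric label lies in ``[0, 1]``).  Non-numeric internal labels are
    preserved as node names.  Quoted labels and square-bracket comments
    are tolerated (comments discarded).
    """
    if support_scale not in ("auto", "percent", "fraction"):
        raise ValueError(f"unknown support_scale: {support_scale!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=False,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several reader error types
        msg = str(exc)
        if "Duplicate taxon labels" in msg:
            label = msg.rsplit("Duplicate taxon labels:", 1)[-1].strip()
            raise NewickParseError(f"duplicate leaf label: {label}") from exc
        raise NewickParseError(msg) from exc

    raw_supports: list[float] = []
    pairs: list[tuple[object, Node, bool]] = []  # (dendropy node, our node, is_root)

    def convert(dnode, is_root: bool) -> Node:
        if not dnode.child_nodes():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            return Node(label=label, length=dnode.edge.length)
        children = [convert(dc, False) for dc in dnode.child_nodes()]
        sup = _coerce_support(dnode.label) if dnode.label else None
        label = None if sup is not None else dnode.label
        node = Node(label=label, children=children, length=dnode.edge.length)
        if sup is not None and not is_root:
            raw_supports.append(sup)
        pairs.append((dnode, node, is_root))
        return node

    root = convert(dtree.seed_node, True)

    if support_scale == "fraction":
        scale = 100.0
    elif support_scale == "percent":
        scale = 1.0
    else:
        scale = 100.0 if raw_supports and all(0.0 <= s <= 1.0 for s in raw_supports) else 1.0
        if scale == 100.0 and raw_supports:
            logger.info("newick supports all in [0, 1]; rescaling to percent (x100)")

    for dnode, node, is_root in pairs:
        if is_root:
            continue
        sup = _coerce_support(dnode.label) if dnode.label else None
        if sup is not None:
            scaled = int(round(sup * scale))
            if not (0 <= scaled <= 100):
                raise NewickParseError(
                    f"support {sup} out of range after scaling ({scaled})"
                )
            node.support = scaled

    try:
        tree = PhyloTree(root)
    except TreeError as exc:
        raise NewickParseError(str(exc)) from exc
    return tree.canonicalize()


_QUOTE_NEEDED = re.compile(r"[\s()\[\]{}:;,'\"]")


def _fmt_label(label: str) -> str:
    if _QUOTE_NEEDED.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_length(x: float) -> str:
    s = f"{x:.10g}"
    return s


def serialize_newick(tree: PhyloTree) -> str:
    """Serialize to newick with supports as internal node labels."""

    def rec(node: Node, is_root: bool) -> str:
        if node.is_leaf():
            s = _fmt_label(node.label)
        else:
            inner = ",".join(rec(c, False) for c in node.children)
            if not is_root and node.support is not None:
                tag = str(node.support)
            elif node.label:
                tag = _fmt_label(node.label)
            else:
                tag = ""
            s = f"({inner}){tag}"
        if node.length is not None:
            s += f":{_fmt_length(node.length)}"
        return s

    return rec(tree.root, True) + ";"


# ----------------------------------------------------------------------
# Rooting
# ----------------------------------------------------------------------
def root_with_outgroup(tree: PhyloTree, outgroup: Iterable[str]) -> PhyloTree:
    """Re-root on the edge separating *outgroup* from the remaining taxa.

    The outgroup must form a clade in the unrooted sense (i.e. the split
    outgroup-vs-rest must be displayed by the tree); the unrooted
    bipartition set is unchanged by re-rooting.
    """
    og = frozenset(outgroup)
    taxa = tree.leaf_labels
    if not og:
        raise TreeError("empty outgroup")
    extra = og - taxa
    if extra:
        raise TreeError(f"outgroup taxa absent from tree: {sorted(extra)}")
    if og == taxa:
        raise TreeError("outgroup cannot comprise all taxa")

    work = tree.copy()
    clades = work.clades()
    target = None
    for node in work.postorder():
        if node is not work.root and clades[node] in (og, taxa - og):
            target = node
            break
    if target is None:
        witnesses = sorted(og)
        raise TreeError(f"outgroup {witnesses} is not a clade (unrooted) in the tree")

    if target.parent is work.root and len(work.root.children) == 2:
        # already rooted on this edge
        return PhyloTree(work.root).canonicalize()

    # Undirected re-rooting: build adjacency with edge attributes taken from
    # the child end of each original edge, split the edge above `target`
    # with a new root, and rebuild by traversal.  Supports travel with
    # their (undirected) edge.
    adj: dict[int, list[tuple[Node, Optional[float], Optional[int]]]] = {}
    node_of: dict[int, Node] = {}

    def add_edge(a: Node, b: Node, length, support) -> None:
        adj.setdefault(id(a), []).append((b, length, support))
        adj.setdefault(id(b), []).append((a, length, support))
        node_of[id(a)] = a
        node_of[id(b)] = b

    for node in work.postorder():
        for c in node.children:
            add_edge(node, c, c.length, c.support)

    u, v = target.parent, target  # edge to split
    half = (target.length / 2.0) if target.length is not None else None

    def build(cur: Node, prev_id: int, length, support) -> Node:
        """Rebuild the subtree hanging off `cur`, entered via an edge with
        the given attributes, walking away from `prev_id`."""
        neighbors = [(n, l, s) for (n, l, s) in adj[id(cur)] if id(n) != prev_id]
        if not neighbors:
            return Node(cur.label, length=length, support=None)
        if len(neighbors) == 1 and cur is work.root:
            # old root passed through: suppress, merging the two edges
            (n, l, s) = neighbors[0]
            merged_len = None
            if length is not None or l is not None:
                merged_len = (length or 0.0) + (l or 0.0)
            merged_sup = support if s is None else (s if support is None else max(s, support))
            return build(n, id(cur), merged_len, merged_sup)
        kids = [build(n, id(cur), l, s) for (n, l, s) in neighbors]
        label = cur.label if cur.is_leaf() else None
        return Node(label, kids, length, support)

    # prevent traversal across the split edge
    adj[id(u)] = [(n, l, s) for (n, l, s) in adj[id(u)] if n is not v]
    adj[id(v)] = [(n, l, s) for (n, l, s) in adj[id(v)] if n is not u]

    # the split edge keeps its support, carried by the (internal) root children
    edge_sup = target.support
    side_v = build(v, -1, half, None)
    side_u = build(u, -1, half, None)
    new_root = Node(children=[side_v, side_u])
    for c in new_root.children:
        c.support = edge_sup if not c.is_leaf() else None
    return PhyloTree(new_root).canonicalize()


# ----------------------------------------------------------------------
# Collapsing and pruning
# ----------------------------------------------------------------------
def collapse_low_support(tree: PhyloTree, threshold: float) -> PhyloTree:
    """Contract every internal non-root edge with support strictly below
    *threshold* into a polytomy.

    Edges with support >= threshold, and edges with *no* support value,
    are retained.  The leaf set is unchanged.
    """
    if not (0 <= threshold <= 100):
        raise TreeError(f"threshold {threshold} outside [0, 100]")
    work = tree.copy()
    for node in list(work.postorder()):
        if node is work.root or node.is_leaf():
            continue
        if node.support is not None and node.support < threshold:
            parent = node.parent
            idx = parent.children.index(node)
            for c in node.children:
                c.parent = parent
            parent.children[idx : idx + 1] = node.children
    return PhyloTree(work.root).canonicalize()


def prune_to_taxa(tree: PhyloTree, taxa: Iterable[str]) -> PhyloTree:
    """Restrict the tree to the given leaves, suppressing unary nodes.

    When two edges merge, branch lengths add and the surviving edge keeps
    the larger of the two supports (conservative for threshold tests).
    """
    keep = frozenset(taxa)
    missing = keep - tree.leaf_labels
    if missing:
        raise TreeError(f"taxa absent from tree: {sorted(missing)}")
    if not keep:
        raise TreeError("cannot prune to an empty taxon set")

    def rec(node: Node) -> Optional[Node]:
        if node.is_leaf():
            if node.label in keep:
                return Node(node.label, length=node.length)
            return None
        kids = [k for k in (rec(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            child = kids[0]
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            if node.support is not None and (
                child.support is None or node.support > child.support
            ):
                child.support = node.support
            return child
        new = Node(node.label, kids, node.length, node.support)
        return new

    root = rec(tree.root)
    if root is None or root.is_leaf():
        raise TreeError("pruning left fewer than 2 leaves")
    root.support = None
    root.length = None
    if len(root.children) == 1:  # pragma: no cover - defensive
        root = root.children[0]
        root.parent = None
    root.parent = None
    return PhyloTree(root).canonicalize()
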