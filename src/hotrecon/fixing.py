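"""Error-aware topology adjustment against a reference tree.

Brings an associate tree (a gene or operon tree) into agreement with a
reference wherever the associate's own bootstrap support does not
contradict it: edges supported below a negotiability threshold are
collapsed, and the resulting polytomies are re-resolved so as to
minimize the DTL reconciliation cost against the reference.

For polytomies with up to ``EXHAUSTIVE_LIMIT`` children every rooted
resolution (``(2k-3)!!`` of them) is scored; larger polytomies are
resolved by greedy stepwise insertion.  The original resolution is kept
whenever it is at least as good as the best rearrangement, so the
reconciliation cost never increases, well-supported structure is never
touched, and fixing is idempotent.

This is a support-based stand-in for alignment-aware tree correction:
per-site statistical tests need the original alignments, whereas
bootstrap supports travel with the tree files themselves; edges below
the threshold are treated as statistically negotiable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence, Union

from .reconcile import CostScheme, dtl_reconcile
from .tree import Bipartition, Node, PhyloTree, TreeError, bipartition_set, prune_to_taxa

logger = logging.getLogger("hotrecon")

__all__ = ["FixResult", "fix_tree", "fix_all", "EXHAUSTIVE_LIMIT"]

#: largest polytomy resolved by exhaustive enumeration ((2*6-3)!! = 945)
EXHAUSTIVE_LIMIT = 6

# a resolution "shape" is a group index or a pair of shapes
_Shape = Union[int, tuple]


@dataclass
class FixResult:
    """Outcome of fixing one associate tree against a reference."""

    tree: PhyloTree
    removed_bipartitions: list[Bipartition]
    added_bipartitions: list[Bipartition]
    cost_before: float
    cost_after: float
    support_threshold: float

    @property
    def changed(self) -> bool:
        return bool(self.removed_bipartitions or self.added_bipartitions)


# ----------------------------------------------------------------------
# resolution shapes
# ----------------------------------------------------------------------
def _insert_leaf(shape: _Shape, leaf: int) -> Iterator[_Shape]:
    """All shapes obtained by grafting `leaf` onto any edge of `shape`
    (including above its root)."""
    yield (shape, leaf)
    if isinstance(shape, tuple):
        left, right = shape
        for s in _insert_leaf(left, leaf):
            yield (s, right)
        for s in _insert_leaf(right, leaf):
            yield (left, s)


def _all_shapes(k: int) -> Iterator[_Shape]:
    """All (2k-3)!! rooted binary shapes over k group indices."""

    def rec(shape: _Shape, nxt: int) -> Iterator[_Shape]:
        if nxt == k:
            yield shape
            return
        for s in _insert_leaf(shape, nxt):
            yield from rec(s, nxt + 1)

    yield from rec(0, 1)


def _copy_subtree(node: Node) -> Node:
    return Node(
        node.label,
        [_copy_subtree(c) for c in node.children],
        node.length,
        node.support,
    )


def _shape_to_node(shape: _Shape, groups: Sequence[Node]) -> Node:
    """Materialize a shape; join nodes are new, unsupported, lengthless."""
    if isinstance(shape, int):
        return _copy_subtree(groups[shape])
    left, right = shape
    return Node(children=[_shape_to_node(left, groups), _shape_to_node(right, groups)])


def _subtree_key(node: Node) -> tuple:
    if node.is_leaf():
        return ("L", node.label)
    return ("I", tuple(sorted(_subtree_key(c) for c in node.children)))


def _subtree_leafset(node: Node) -> frozenset:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf():
            out.append(n.label)
        else:
            stack.extend(n.children)
    return frozenset(out)


# ----------------------------------------------------------------------
# negotiable regions
# ----------------------------------------------------------------------
def _is_weak(node: Node, threshold: float) -> bool:
    return (
        node.parent is not None
        and not node.is_leaf()
        and node.support is not None
        and node.support < threshold
    )


def _region_groups(top: Node, threshold: float) -> list[Node]:
    """Child groups of the polytomy formed at `top` when its weak
    descendant edges are contracted (an existing polytomy counts too)."""
    groups: list[Node] = []

    def gather(n: Node) -> None:
        for c in n.children:
            if _is_weak(c, threshold):
                gather(c)
            else:
                groups.append(c)

    gather(top)
    return groups


def _region_tops(tree: PhyloTree, threshold: float) -> list[frozenset]:
    """Leaf sets of region-top nodes, in postorder."""
    tops = []
    for node in tree.postorder():
        if node.is_leaf() or _is_weak(node, threshold):
            continue
        groups = _region_groups(node, threshold)
        if len(groups) > 2:
            tops.append(_subtree_leafset(node))
    return tops


def _locate(tree: PhyloTree, leafset: frozenset) -> Optional[Node]:
    clades = tree.clades()
    for node in tree.postorder():
        if clades[node] == leafset:
            return node
    return None


def _replace_children(tree: PhyloTree, top: Node, resolution: Node) -> PhyloTree:
    """Copy `tree` with the region at `top` replaced by `resolution`
    (the resolution's root becomes `top` itself, keeping its edge)."""
    new_children = (
        list(resolution.children)
        if not resolution.is_leaf() and resolution.label is None
        else [resolution]
    )

    def rec(node: Node) -> Node:
        if node is top:
            clone = Node(node.label, [], node.length, node.support)
            for c in new_children:
                clone.add_child(_copy_subtree(c))
            return clone
        return Node(node.label, [rec(c) for c in node.children], node.length, node.support)

    return PhyloTree(rec(tree.root))


# ----------------------------------------------------------------------
# fixing
# ----------------------------------------------------------------------
def fix_tree(
    assoc: PhyloTree,
    ref: PhyloTree,
    support_threshold: float = 70,
    costs: CostScheme = CostScheme(),
) -> FixResult:
    """Fix an associate tree against a binary reference tree.

    Taxa absent from either tree are pruned from both (logged).  Returns
    the fixed tree plus the bipartitions removed/added and the DTL
    reconciliation cost before and after.  Fixing never re-roots the
    associate tree and never touches edges supported at or above the
    threshold (or edges with no support value).
    """
    if not (0 <= support_threshold <= 100):
        raise TreeError(f"threshold {support_threshold} outside [0, 100]")
    if not ref.is_binary():
        raise TreeError("reference tree must be binary")

    common = assoc.leaf_labels & ref.leaf_labels
    if len(common) < 3:
        raise TreeError("fewer than 3 shared taxa between associate and reference")
    if common != assoc.leaf_labels or common != ref.leaf_labels:
        logger.info(
            "pruning to %d shared taxa (associate had %d, reference %d)",
            len(common), len(assoc.leaf_labels), len(ref.leaf_labels),
        )
    work = (
        prune_to_taxa(assoc, common)
        if assoc.leaf_labels != common
        else assoc.copy().canonicalize()
    )
    ref_p = prune_to_taxa(ref, common) if ref.leaf_labels != common else ref

    cost_before: Optional[float] = (
        dtl_reconcile(work, ref_p, costs=costs).cost if work.is_binary() else None
    )

    current = work
    for top_leaves in _region_tops(work, support_threshold):
        top = _locate(current, top_leaves)
        if top is None:  # pragma: no cover - defensive
            continue
        groups = _region_groups(top, support_threshold)
        k = len(groups)
        if k <= 2:
            continue

        best_tree = None
        best_cost = None
        best_key = None
        if k <= EXHAUSTIVE_LIMIT:
            for shape in _all_shapes(k):
                cand = _shape_to_node(shape, groups)
                cand_tree = _replace_children(current, top, cand)
                c = dtl_reconcile(cand_tree, ref_p, costs=costs).cost
                key = _subtree_key(cand_tree.root)
                if (
                    best_cost is None
                    or c < best_cost - 1e-9
                    or (abs(c - best_cost) <= 1e-9 and key < best_key)
                ):
                    best_tree, best_cost, best_key = cand_tree, c, key
        else:
            best_tree, best_cost = _greedy_resolution(current, top, groups, ref_p, costs)

        # keep the original arrangement when it is binary and at least as good
        if len(top.children) == 2 and current.is_binary():
            orig_cost = dtl_reconcile(current, ref_p, costs=costs).cost
            if best_cost is None or orig_cost <= best_cost + 1e-9:
                continue
        current = best_tree.canonicalize()

    if not current.is_binary():  # pragma: no cover - defensive
        raise TreeError("fixing failed to produce a binary tree")

    cost_after = dtl_reconcile(current, ref_p, costs=costs).cost
    if cost_before is None:
        cost_before = cost_after
    if cost_after > cost_before + 1e-9:  # pragma: no cover - internal invariant
        raise AssertionError("fixing increased the reconciliation cost")

    before_bps = {bp for bp, _ in bipartition_set(work)}
    after_bps = {bp for bp, _ in bipartition_set(current)}
    return FixResult(
        tree=current,
        removed_bipartitions=sorted(before_bps - after_bps),
        added_bipartitions=sorted(after_bps - before_bps),
        cost_before=float(cost_before),
        cost_after=float(cost_after),
        support_threshold=support_threshold,
    )


def _greedy_resolution(
    current: PhyloTree,
    top: Node,
    groups: list[Node],
    ref: PhyloTree,
    costs: CostScheme,
) -> tuple[PhyloTree, float]:
    """Stepwise insertion for polytomies above the exhaustive limit.

    Groups are inserted in canonical order; each step grafts the next
    group at the attachment point minimizing the reconciliation cost of
    the partial tree (the reference pruned to the taxa present so far).
    """
    order = sorted(range(len(groups)), key=lambda i: _subtree_key(groups[i]))
    shape: _Shape = (order[0], order[1])
    for idx in order[2:]:
        best_shape = None
        best_cost = None
        best_key = None
        for cand_shape in _insert_leaf(shape, idx):
            cand = _shape_to_node(cand_shape, groups)
            cand_tree = _replace_children(current, top, cand)
            shared = cand_tree.leaf_labels & ref.leaf_labels
            ref_eval = prune_to_taxa(ref, shared) if shared != ref.leaf_labels else ref
            c = dtl_reconcile(cand_tree, ref_eval, costs=costs).cost
            key = _subtree_key(cand)
            if (
                best_cost is None
                or c < best_cost - 1e-9
                or (abs(c - best_cost) <= 1e-9 and key < best_key)
            ):
                best_shape, best_cost, best_key = cand_shape, c, key
        shape = best_shape
    final = _replace_children(current, top, _shape_to_node(shape, groups))
    return final, dtl_reconcile(final, ref, costs=costs).cost


def fix_all(
    gene_trees: Sequence[PhyloTree],
    ref: PhyloTree,
    support_threshold: float = 70,
    costs: CostScheme = CostScheme(),
) -> list[FixResult]:
    """Elementwise :func:`fix_tree` over a collection of associate trees."""
    return [fix_tree(t, ref, support_threshold, costs) for t in gene_trees]
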