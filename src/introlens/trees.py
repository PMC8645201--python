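"""Rooted-tree algorithms on top of dendropy.

Trees are ordinary :class:`dendropy.Tree` objects read from Newick.  Numeric
internal-node labels are interpreted as support values (the SH-aLRT
convention used by IQ-TREE and similar programs).  All functions treat the
tree as rooted; branch lengths are in whatever units the input uses
(millions of years for dated species trees, substitutions/site for gene
trees).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "RootedTree",
    "Triad",
    "TreeValidationError",
    "parse_tree",
    "read_trees",
    "write_tree",
    "node_support",
    "collapse_low_support",
    "extract_triads",
    "count_exclusive_triads",
    "prune_to_representatives",
    "node_age",
    "tree_height",
    "is_ultrametric",
    "bm_covariance",
    "triads_to_tsv",
]

logger = logging.getLogger(__name__)

#: Alias used throughout the package; any rooted dendropy tree qualifies.
RootedTree = dendropy.Tree

#: Relative tolerance (fraction of tree height) for ultrametricity checks.
ULTRAMETRIC_RTOL = 1e-6


class TreeValidationError(ValueError):
    """Raised when a tree violates a structural precondition."""


@dataclass(frozen=True)
class Triad:
    """An exclusive species triad: a sister pair plus a third species.

    ``p1`` and ``p2`` are the two tips of the cherry inside the triad clade,
    ``p3`` the remaining tip, and ``outgroup`` the most closely related tip
    outside the clade (``None`` when the triad node has no tip-bearing
    sister, in which case ``outgroup_missing`` is set).  Ages are in the
    time units of the source tree and are NaN when the tree is undated.
    """

    triad_id: str
    p1: str
    p2: str
    p3: str
    outgroup: str | None
    crown_age: float = math.nan
    sister_age: float = math.nan

    @property
    def internode(self) -> float:
        return self.crown_age - self.sister_age

    @property
    def outgroup_missing(self) -> bool:
        return self.outgroup is None

    @property
    def species(self) -> tuple[str, str, str]:
        return (self.p1, self.p2, self.p3)


def parse_tree(text: str) -> RootedTree:
    """Parse a single Newick string into a rooted tree.

    Numeric internal labels are stored on ``node.label`` and read back by
    :func:`node_support`.  Raises :class:`TreeValidationError` for malformed
    input or duplicate tip labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeValidationError(f"malformed Newick: {exc}") from exc
    _check_unique_tips(tree)
    return tree


def read_trees(path: str) -> list[RootedTree]:
    """Read one or more Newick trees from a file (one per line or ';'-separated)."""
    trees = dendropy.TreeList.get(
        path=path,
        schema="newick",
        suppress_internal_node_taxa=True,
        rooting="force-rooted",
    )
    out = list(trees)
    for t in out:
        _check_unique_tips(t)
    return out


def write_tree(tree: RootedTree) -> str:
    """Serialize to Newick; internal-node supports are written as labels."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def _check_unique_tips(tree: RootedTree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise TreeValidationError(f"duplicate tip labels: {dupes}")


def node_support(node: dendropy.Node) -> float | None:
    """Support value for an internal node, or ``None`` if absent/non-numeric."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def collapse_low_support(tree: RootedTree, threshold: float = 80.0) -> RootedTree:
    """Contract internal edges whose child node has support strictly below *threshold*.

    Children of a collapsed node are re-attached to its parent with their own
    branch lengths unchanged.  Nodes without a support value are never
    collapsed; the comparison is strict (< threshold collapsed, == kept).
    Returns a new tree; the input is untouched.  The tip set is preserved.
    """
    out = tree.clone(depth=1)
    to_collapse = []
    for node in out.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        sup = node_support(node)
        if sup is not None and sup < threshold:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return out


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def extract_triads(
    tree: RootedTree,
    completeness: Mapping[str, float] | None = None,
) -> list[Triad]:
    """Extract all exclusive triads (monophyletic 3-species clades).

    One triad is returned for every internal node with exactly three
    descendant tips that is resolved into a cherry plus a third tip.  The
    outgroup is the tip of the triad node's sister clade with the highest
    *completeness* (ties broken by the lexicographically smallest label);
    with no completeness table, all tips tie and the smallest label wins.
    Polytomous three-tip clades are skipped with a warning.  Triads are
    returned in preorder traversal order with ids ``T001``, ``T002``, ...
    """
    completeness = completeness or {}
    ultra = is_ultrametric(tree)
    if ultra:
        height = tree_height(tree)
        depths = _root_distances(tree)
    triads: list[Triad] = []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        leaves = _leafset(node)
        if len(leaves) != 3:
            continue
        children = node.child_nodes()
        cherry = None
        third = None
        if len(children) == 2:
            for child in children:
                cl = _leafset(child)
                if len(cl) == 2 and len(child.child_nodes()) == 2:
                    cherry = child
                elif len(cl) == 1:
                    third = child
        if cherry is None or third is None:
            logger.warning(
                "skipping unresolved 3-tip clade %s", sorted(leaves)
            )
            continue
        p1, p2 = sorted(l.taxon.label for l in cherry.leaf_iter())
        p3 = next(third.leaf_iter()).taxon.label
        outgroup = _pick_outgroup(node, completeness)
        if ultra:
            crown = height - depths[id(node)]
            sister = height - depths[id(cherry)]
        else:
            crown = sister = math.nan
        triads.append(
            Triad(
                triad_id=f"T{len(triads) + 1:03d}",
                p1=p1,
                p2=p2,
                p3=p3,
                outgroup=outgroup,
                crown_age=crown,
                sister_age=sister,
            )
        )
    return triads


def _pick_outgroup(
    triad_node: dendropy.Node, completeness: Mapping[str, float]
) -> str | None:
    parent = triad_node.parent_node
    if parent is None:
        return None
    sister_tips: set[str] = set()
    for sib in parent.child_nodes():
        if sib is not triad_node:
            sister_tips |= _leafset(sib)
    if not sister_tips:
        return None
    # max completeness, then lexicographically smallest label
    return min(sister_tips, key=lambda s: (-completeness.get(s, 0.0), s))


def count_exclusive_triads(tree: RootedTree) -> int:
    """Census of internal nodes with exactly three descendant tips."""
    return sum(
        1
        for node in tree.preorder_node_iter()
        if not node.is_leaf() and len(_leafset(node)) == 3
    )


def prune_to_representatives(tree: RootedTree, keep: Iterable[str]) -> RootedTree:
    """Induced subtree on *keep*; unary nodes suppressed, lengths summed."""
    keep = set(keep)
    tips = {l.taxon.label for l in tree.leaf_node_iter()}
    unknown = sorted(keep - tips)
    if unknown:
        raise TreeValidationError(f"species not in tree: {unknown}")
    if len(keep) < 2:
        raise TreeValidationError("need at least two species to prune to")
    out = tree.extract_tree_with_taxa_labels(labels=keep)
    out.suppress_unifurcations()
    return out


def _root_distances(tree: RootedTree) -> dict[int, float]:
    dist: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            dist[id(node)] = 0.0
        else:
            bl = node.edge.length or 0.0
            dist[id(node)] = dist[id(node.parent_node)] + bl
    return dist


def tree_height(tree: RootedTree) -> float:
    """Maximum root-to-tip path length."""
    dist = _root_distances(tree)
    return max(dist[id(l)] for l in tree.leaf_node_iter())


def is_ultrametric(tree: RootedTree, rtol: float = ULTRAMETRIC_RTOL) -> bool:
    if any(e.length is None for e in tree.preorder_edge_iter() if e.head_node.parent_node):
        return False
    dist = _root_distances(tree)
    tip_d = [dist[id(l)] for l in tree.leaf_node_iter()]
    height = max(tip_d)
    if height == 0:
        return False
    return max(tip_d) - min(tip_d) <= rtol * height


def node_age(tree: RootedTree, node: dendropy.Node) -> float:
    """Age of a node on a dated (ultrametric) tree: height minus root distance."""
    if not is_ultrametric(tree):
        raise TreeValidationError(
            "node ages require an ultrametric tree "
            f"(tolerance {ULTRAMETRIC_RTOL:g} x height)"
        )
    dist = _root_distances(tree)
    height = max(dist[id(l)] for l in tree.leaf_node_iter())
    return height - dist[id(node)]


def bm_covariance(tree: RootedTree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance among tips.

    ``V[i, j]`` is the root-to-MRCA(i, j) path length (shared evolutionary
    history); the diagonal holds root-to-tip distances.  Returns the tip
    labels (sorted) and the matrix in that order.
    """
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    if tree_height(tree) <= 0:
        raise TreeValidationError("zero-height tree has no Brownian covariance")
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))
    dist = _root_distances(tree)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            V[idx[node.taxon.label], idx[node.taxon.label]] = dist[id(node)]
            continue
        children = node.child_nodes()
        depth = dist[id(node)]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                la = [idx[l.taxon.label] for l in children[a].leaf_iter()]
                lb = [idx[l.taxon.label] for l in children[b].leaf_iter()]
                for i in la:
                    for j in lb:
                        V[i, j] = V[j, i] = depth
    return labels, V


def triads_to_tsv(triads: Sequence[Triad]) -> str:
    """Render triads as a TSV table (header included)."""
    lines = ["triad_id\tp1\tp2\tp3\toutgroup\tcrown_age\tsister_age\tinternode"]
    for t in triads:
        og = t.outgroup if t.outgroup is not None else "NA"
        lines.append(
            f"{t.triad_id}\t{t.p1}\t{t.p2}\t{t.p3}\t{og}"
            f"\t{t.crown_age:.6g}\t{t.sister_age:.6g}\t{t.internode:.6g}"
        )
    return "\n".join(lines) + "\n"
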