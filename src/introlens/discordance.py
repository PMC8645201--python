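"""Gene-tree concordance/conflict counting against a species tree.

For every internal node of the species (consensus) tree, each gene tree is
classified as concordant, conflicting, or uninformative with respect to the
node's defining clade, in the phyparts sense: the clade is first restricted
to the taxa actually present in the gene tree, a gene tree is concordant
when it contains a clade with exactly that restricted tip set, conflicting
when some resolved gene-tree clade partially overlaps it, and uninformative
otherwise (too few shared taxa, or only polytomies where resolution would be
needed).  The per-node discordance ratio is

    ratio = n_conflicting / (n_concordant + n_conflicting),

i.e. uninformative gene trees never enter the denominator.

A tip-level, time-integrated summary ("DR-analog") averages the ratios of
all nodes on a tip's root path with weights halving at each step rootward:
node j (1 = the node immediately above the tip) gets weight 2**-(j-1), and
weights are renormalized over the nodes that actually have a defined ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .trees import RootedTree, collapse_low_support

__all__ = [
    "NodeConcordance",
    "TipDiscordance",
    "classify_clade",
    "summarize_concordance",
    "tip_integrated_discordance",
    "group_average",
    "species_tree_clades",
    "node_table_tsv",
]

CONCORDANT = "concordant"
CONFLICTING = "conflicting"
UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class NodeConcordance:
    """Concordance counts for one species-tree node across gene trees."""

    node_id: str
    clade: frozenset[str]
    n_concordant: int
    n_conflicting: int
    n_uninformative: int

    @property
    def n_resolved(self) -> int:
        return self.n_concordant + self.n_conflicting

    @property
    def ratio(self) -> float:
        """Discordance ratio; NaN when no gene tree is resolved at the node."""
        if self.n_resolved == 0:
            return math.nan
        return self.n_conflicting / self.n_resolved


@dataclass(frozen=True)
class TipDiscordance:
    species: str
    value: float
    n_nodes_used: int

    @property
    def missing(self) -> bool:
        return self.n_nodes_used == 0


def _gene_tree_clades(tree: RootedTree) -> tuple[frozenset[str], set[frozenset[str]]]:
    """Taxon set and the set of non-trivial rooted clades of a gene tree."""
    taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    clades: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        c = frozenset(l.taxon.label for l in node.leaf_iter())
        if 2 <= len(c) < len(taxa):
            clades.add(c)
    return taxa, clades


def classify_clade(
    clade: Iterable[str],
    gene_tree: RootedTree,
    *,
    universe: Iterable[str] | None = None,
) -> str:
    """Classify a species-tree clade against one gene tree.

    Missing taxa are forgiven: the clade is restricted to the gene tree's
    taxa before comparison.  Returns ``"concordant"``, ``"conflicting"`` or
    ``"uninformative"``.
    """
    clade = frozenset(clade)
    if universe is not None:
        extra = clade - set(universe)
        if extra:
            raise ValueError(f"clade contains unknown species: {sorted(extra)}")
    taxa, gclades = _gene_tree_clades(gene_tree)
    return _classify_restricted(clade, taxa, gclades)


def _classify_restricted(
    clade: frozenset[str],
    gene_taxa: frozenset[str],
    gene_clades: set[frozenset[str]],
) -> str:
    s = clade & gene_taxa
    if len(s) < 2 or len(gene_taxa - s) < 1:
        return UNINFORMATIVE
    if s in gene_clades:
        return CONCORDANT
    for c in gene_clades:
        inter = c & s
        if inter and (c - s) and (s - c):
            # c and s partially overlap: no rooted tree contains both
            return CONFLICTING
    return UNINFORMATIVE


def species_tree_clades(species_tree: RootedTree) -> list[tuple[str, frozenset[str]]]:
    """(node_id, defining clade) for every internal node, preorder.

    Node ids are ``N001``, ``N002``, ... in preorder so that output tables
    are stable across runs on the same tree.
    """
    out = []
    for node in species_tree.preorder_node_iter():
        if node.is_leaf():
            continue
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        out.append((f"N{len(out) + 1:03d}", clade))
    return out


def summarize_concordance(
    species_tree: RootedTree,
    gene_trees: Sequence[RootedTree],
    support_threshold: float | None = 80.0,
) -> list[NodeConcordance]:
    """Count concordant/conflicting/uninformative gene trees per species-tree node.

    Gene trees are first collapsed at *support_threshold* (pass ``None`` to
    use them as given), so that poorly supported gene-tree clades cannot
    create spurious conflict.
    """
    if not gene_trees:
        raise ValueError("empty gene-tree list")
    if support_threshold is not None:
        gene_trees = [collapse_low_support(g, support_threshold) for g in gene_trees]
    prepared = [_gene_tree_clades(g) for g in gene_trees]
    records = []
    for node_id, clade in species_tree_clades(species_tree):
        counts = {CONCORDANT: 0, CONFLICTING: 0, UNINFORMATIVE: 0}
        for taxa, gclades in prepared:
            counts[_classify_restricted(clade, taxa, gclades)] += 1
        records.append(
            NodeConcordance(
                node_id=node_id,
                clade=clade,
                n_concordant=counts[CONCORDANT],
                n_conflicting=counts[CONFLICTING],
                n_uninformative=counts[UNINFORMATIVE],
            )
        )
    return records


def node_ratio_map(
    species_tree: RootedTree, records: Sequence[NodeConcordance]
) -> dict[frozenset[str], float]:
    """Map each node's defining clade to its discordance ratio (NaN kept)."""
    return {r.clade: r.ratio for r in records}


def tip_integrated_discordance(
    species_tree: RootedTree,
    node_values: Mapping[frozenset[str], float],
) -> list[TipDiscordance]:
    """Tip-level weighted average of subtending node values (DR-analog).

    For each tip, nodes on its root path are taken tipward to rootward;
    node j among those with a defined (non-NaN) value gets weight
    2**-(j-1); the weighted mean is returned.  Tips with no usable node are
    flagged missing (value NaN).
    """
    out = []
    for leaf in species_tree.leaf_node_iter():
        values = []
        node = leaf.parent_node
        while node is not None:
            clade = frozenset(l.taxon.label for l in node.leaf_iter())
            v = node_values.get(clade, math.nan)
            if not math.isnan(v):
                values.append(v)
            node = node.parent_node
        if not values:
            out.append(TipDiscordance(leaf.taxon.label, math.nan, 0))
            continue
        weights = [2.0 ** -(j) for j in range(len(values))]
        total = sum(weights)
        value = sum(w * v for w, v in zip(weights, values)) / total
        out.append(TipDiscordance(leaf.taxon.label, value, len(values)))
    return out


def group_average(
    tip_values: Sequence[TipDiscordance],
    membership: Mapping[str, Iterable[str]],
) -> dict[str, float]:
    """Unweighted mean tip value per group (e.g. per equal-area grid cell).

    Species without a usable tip value are skipped; a group with no scored
    member maps to NaN.
    """
    by_species = {t.species: t.value for t in tip_values if not t.missing}
    out: dict[str, float] = {}
    for group, members in membership.items():
        vals = [by_species[s] for s in members if s in by_species]
        out[group] = sum(vals) / len(vals) if vals else math.nan
    return out


def node_table_tsv(records: Sequence[NodeConcordance]) -> str:
    """Per-node concordance table as TSV (clade as comma-joined sorted tips)."""
    lines = ["node_id\tclade\tn_concordant\tn_conflicting\tn_uninformative\tratio"]
    for r in records:
        ratio = f"{r.ratio:.6g}" if not math.isnan(r.ratio) else "NA"
        lines.append(
            f"{r.node_id}\t{','.join(sorted(r.clade))}\t{r.n_concordant}"
            f"\t{r.n_conflicting}\t{r.n_uninformative}\t{ratio}"
        )
    return "\n".join(lines) + "\n"
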