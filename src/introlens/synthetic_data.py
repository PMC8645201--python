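"""Distribution-correct synthetic inputs for every pipeline stage.

Three generators cover the three statistical layers:

* :func:`sim_msc_gene_trees` draws gene trees under the multispecies
  coalescent (MSC) on a dated species tree whose branch lengths are in
  coalescent units (one unit = 2N generations).  For a species-tree branch
  of length t with two entering lineages, the probability they fail to
  coalesce within the branch is e^-t, which is what makes the classic
  discordance expectation (2/3) e^-t testable downstream.

* :func:`sim_quartet_freqs` simulates biallelic site patterns for a
  pectinate quartet ((P1, P2), P3), O under the MSC with an optional
  admixture pulse: with probability gamma per locus, the P2 (or P1)
  lineage is reassigned to the P3 population at a contact time more recent
  than the sister split.  gamma = 0 gives E[ABBA] = E[BABA]; gamma > 0
  produces the ABBA (or BABA) excess the D-statistic detects.  Mutations
  are Poisson(theta x tree length), placed uniformly on branches under the
  infinite-sites assumption; one haploid lineage per taxon, so derived
  frequencies are 0/1.

* :func:`sim_traits_on_tree` draws trait tables under a linear SEM whose
  residuals are Brownian motion on a given tree, for calibrating the path
  analysis.

:func:`make_fixture_bundle` writes a self-consistent miniature study (tree,
gene trees, triads, quartet data, ranges, climate rasters, models, config)
exercising every CLI stage.
"""

from __future__ import annotations

import math
import os
import random
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .introgression import AlleleFreqMatrix
from .path_analysis import PathModel
from .predictors import write_esri_ascii
from .trees import RootedTree, bm_covariance, extract_triads, triads_to_tsv, write_tree

__all__ = [
    "QuartetSimConfig",
    "sim_msc_gene_trees",
    "sim_quartet_freqs",
    "sim_traits_on_tree",
    "make_fixture_bundle",
]

# tip order in quartet site patterns
_QUARTET_TAXA = ("p1", "p2", "p3", "out")


@dataclass(frozen=True)
class QuartetSimConfig:
    """Parameters of the quartet MSC + admixture simulator.

    Times are in coalescent units measured back from the present:
    ``t2`` the sister split (P1, P2), ``t1`` the triad crown (> t2),
    ``t_out`` the outgroup split (> t1).  ``theta`` is the expected number
    of mutations per coalescent unit of genealogy per locus; ``gamma`` the
    per-locus probability that the recipient lineage carries P3 ancestry,
    acquired at ``contact_time`` (default half the sister split).
    """

    t2: float = 1.0
    t1: float = 2.0
    t_out: float = 4.0
    theta: float = 3.0
    gamma: float = 0.0
    direction: str = "P3->P2"
    contact_time: float | None = None
    n_loci: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.t2 < self.t1 < self.t_out):
            raise ValueError("need 0 < t2 < t1 < t_out")
        if not 0 <= self.gamma <= 1:
            raise ValueError("gamma must lie in [0, 1]")
        if self.direction not in ("P3->P2", "P3->P1"):
            raise ValueError("direction must be 'P3->P2' or 'P3->P1'")
        tm = self.t2 / 2 if self.contact_time is None else self.contact_time
        if not 0 < tm < self.t2:
            raise ValueError("contact_time must lie in (0, t2)")

    @property
    def tm(self) -> float:
        return self.t2 / 2 if self.contact_time is None else self.contact_time


class _Lineage:
    __slots__ = ("node", "birth")

    def __init__(self, node: dendropy.Node, birth: float):
        self.node = node
        self.birth = birth


def _coalesce_in_branch(
    lineages: list[_Lineage], t_start: float, t_end: float, rng: random.Random
) -> float:
    """Coalesce lineages within [t_start, t_end) at rate k(k-1)/2; returns end time."""
    t = t_start
    while len(lineages) > 1:
        k = len(lineages)
        wait = rng.expovariate(k * (k - 1) / 2.0)
        if t + wait >= t_end:
            break
        t += wait
        i, j = rng.sample(range(k), 2)
        a, b = lineages[i], lineages[j]
        parent = dendropy.Node()
        for lin in (a, b):
            lin.node.edge.length = t - lin.birth
            parent.add_child(lin.node)
        merged = _Lineage(parent, t)
        lineages[:] = [l for l in lineages if l not in (a, b)]
        lineages.append(merged)
    return t_end


def sim_msc_gene_trees(
    species_tree: RootedTree, n_loci: int, seed: int | None = None
) -> list[RootedTree]:
    """Simulate gene trees under the MSC, one haploid lineage per species.

    Species-tree branch lengths are in coalescent units; the tree must be
    ultrametric with positive lengths.  Gene trees come back as rooted,
    ultrametric dendropy trees with tips labeled by species.
    """
    rng = random.Random(seed)
    # species-tree scaffold: postorder list of (node ages, children indices)
    from .trees import _root_distances, tree_height  # internal helpers

    height = tree_height(species_tree)
    depth = _root_distances(species_tree)
    trees = []
    for _ in range(n_loci):
        tns = dendropy.TaxonNamespace()
        pending: dict[int, list[_Lineage]] = {}
        for node in species_tree.postorder_node_iter():
            age = height - depth[id(node)]
            if node.is_leaf():
                tip = dendropy.Node()
                tip.taxon = tns.require_taxon(label=node.taxon.label)
                lineages = [_Lineage(tip, age)]
            else:
                lineages = []
                for child in node.child_nodes():
                    lineages.extend(pending.pop(id(child)))
            if node.parent_node is None:
                _coalesce_in_branch(lineages, age, math.inf, rng)
                root_lineage = lineages[0]
            else:
                parent_age = height - depth[id(node.parent_node)]
                _coalesce_in_branch(lineages, age, parent_age, rng)
                pending[id(node)] = lineages
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.seed_node = root_lineage.node
        trees.append(tree)
    return trees


def _sim_quartet_genealogy(
    cfg: QuartetSimConfig, rng: random.Random
) -> list[tuple[int, float]]:
    """One quartet genealogy; returns branches as (tip mask, duration).

    Masks use bit i for taxon i in (P1, P2, P3, O) order.  The branch above
    the overall root is not represented (mutations there are invisible).
    """
    admixed = rng.random() < cfg.gamma
    recipient = 1 if cfg.direction == "P3->P2" else 0
    # lineage state: mask -> (birth time, population)
    # populations: 0..3 own pops, then merges at t2 (0+1), t1 (01+2), t_out (all)
    lineages: dict[int, tuple[float, int]] = {
        1 << i: (0.0, i) for i in range(4)
    }
    branches: list[tuple[int, float]] = []

    def move_pop(pops: set[int], target: int) -> None:
        for mask, (birth, pop) in list(lineages.items()):
            if pop in pops:
                lineages[mask] = (birth, target)

    # events applied at the END of each epoch, looking backward in time
    epochs: list[tuple[float, tuple[set[int], int] | None]] = []
    if admixed:
        # the recipient lineage acquires P3 ancestry at the contact time
        epochs.append((cfg.tm, ({recipient}, 2)))
    epochs += [
        (cfg.t2, ({0, 1}, 0)),
        (cfg.t1, ({0, 2}, 0)),
        (cfg.t_out, ({0, 3}, 0)),
        (math.inf, None),
    ]
    t = 0.0
    for t_end, merge in epochs:
        if t_end <= t:
            continue
        while True:
            by_pop: dict[int, list[int]] = {}
            for mask, (_, pop) in lineages.items():
                by_pop.setdefault(pop, []).append(mask)
            total_rate = sum(
                k * (k - 1) / 2.0 for k in (len(v) for v in by_pop.values())
            )
            if total_rate == 0:
                t = t_end
                break
            wait = rng.expovariate(total_rate)
            if t + wait >= t_end:
                t = t_end
                break
            t += wait
            # choose a population weighted by its pair count, then a pair
            r = rng.random() * total_rate
            for pop, members in sorted(by_pop.items()):
                k = len(members)
                r -= k * (k - 1) / 2.0
                if r < 0:
                    a, b = rng.sample(sorted(members), 2)
                    break
            ba, _ = lineages.pop(a)
            bb, _ = lineages.pop(b)
            branches.append((a, t - ba))
            branches.append((b, t - bb))
            lineages[a | b] = (t, pop)
            if len(lineages) == 1:
                return branches
        if merge is not None:
            pops, target = merge
            move_pop(pops, target)
    raise AssertionError("genealogy failed to coalesce")  # pragma: no cover


def sim_quartet_freqs(cfg: QuartetSimConfig) -> AlleleFreqMatrix:
    """Simulate a quartet allele-frequency matrix under the MSC + admixture.

    Every mutation produces one biallelic site whose derived state is
    carried by the taxa below the mutated branch; loci are labeled
    ``L000001``...  The matrix may legitimately contain zero rows when
    theta is tiny.
    """
    rng = random.Random(cfg.seed)
    np_rng = np.random.default_rng(rng.getrandbits(63))
    rows, loci, positions = [], [], []
    for locus in range(cfg.n_loci):
        branches = _sim_quartet_genealogy(cfg, rng)
        lengths = np.array([b[1] for b in branches])
        total = lengths.sum()
        n_mut = np_rng.poisson(cfg.theta * total)
        if n_mut == 0:
            continue
        picks = np_rng.choice(len(branches), size=n_mut, p=lengths / total)
        locus_id = f"L{locus + 1:06d}"
        for offset, b in enumerate(picks):
            mask = branches[b][0]
            rows.append([float((mask >> i) & 1) for i in range(4)])
            loci.append(locus_id)
            positions.append(offset)
    if not rows:
        return AlleleFreqMatrix(
            np.empty((0, 4)), np.array([], dtype=object), np.array([], dtype=int)
        )
    return AlleleFreqMatrix(
        np.array(rows), np.array(loci, dtype=object), np.array(positions)
    )


def sim_traits_on_tree(
    tree: RootedTree,
    model: PathModel,
    coefficients: dict[tuple[str, str], float],
    residual_sd: dict[str, float],
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a trait table under a linear SEM with Brownian residuals.

    Exogenous variables are unit-rate Brownian motion on the tree; each
    endogenous variable is the coefficient-weighted sum of its parents plus
    a Brownian residual with the stated standard deviation (scaling the
    unit-rate draw).  Rows are indexed by tip label, sorted.
    """
    import networkx as nx

    labels, V = bm_covariance(tree)
    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(V)))
    rng = np.random.default_rng(seed)
    g = model.graph()
    data: dict[str, np.ndarray] = {}
    for var in nx.lexicographical_topological_sort(g):
        bm = L @ rng.standard_normal(len(labels))
        parents = sorted(g.predecessors(var))
        if not parents:
            data[var] = bm
        else:
            mean = np.zeros(len(labels))
            for p in parents:
                mean += coefficients[(p, var)] * data[p]
            data[var] = mean + residual_sd.get(var, 1.0) * bm
    return pd.DataFrame(data, index=labels)


# ---------------------------------------------------------------------------
# fixture bundle


def _random_dated_tree(
    n_tips: int, seed: int, height: float, min_triads: int
) -> RootedTree:
    """Random birth-death tree scaled to *height*, with enough exclusive triads."""
    from dendropy.model import birthdeath

    for attempt in range(200):
        rng = random.Random(seed * 1000 + attempt)
        tree = birthdeath.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            num_extant_tips=n_tips,
            rng=rng,
        )
        for i, leaf in enumerate(sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)):
            leaf.taxon.label = f"sp{i + 1:02d}"
        # strip internal labels, scale to requested height
        from .trees import tree_height

        h = tree_height(tree)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= height / h
        for node in tree.preorder_node_iter():
            if not node.is_leaf():
                node.label = None
        if len(extract_triads(tree)) >= min_triads:
            return tree
    raise RuntimeError("could not draw a tree with enough triads")


def _block_range(
    rng: random.Random, nrows: int, ncols: int, max_side: int = 4
) -> set[tuple[int, int]]:
    h = rng.randint(2, max_side)
    w = rng.randint(2, max_side)
    r0 = rng.randint(0, nrows - h)
    c0 = rng.randint(0, ncols - w)
    return {(r, c) for r in range(r0, r0 + h) for c in range(c0, c0 + w)}


def make_fixture_bundle(out_dir: str, seed: int = 0, force: bool = False) -> dict[str, str]:
    """Write a miniature, self-consistent study to *out_dir*.

    Contents: a 20-species dated tree (Ma), 200 MSC gene trees with
    synthetic SH-aLRT-style supports, the triad table, quartet
    allele-frequency TSVs for the first five triads (alternating gamma 0
    and 0.3), gridded ranges and a present/LGM raster pair, the three
    default path models, and a TOML config tying it together.  Everything
    is a pure function of *seed*.  Refuses to write into a non-empty
    directory unless *force* is set.  Returns a name -> path map.
    """
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not force:
        raise FileExistsError(f"{out_dir} is not empty (use force=True)")
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name: str, rel: str) -> str:
        paths[name] = os.path.join(out_dir, rel)
        return paths[name]

    rng = random.Random(seed)

    # --- species tree (40 tips, height 20 Ma) and triads; 40 tips gives
    # enough exclusive triads for the path models to stay estimable even
    # when a triad or two drops downstream
    height_ma = 20.0
    tree = _random_dated_tree(40, seed=seed, height=height_ma, min_triads=10)
    with open(p("species_tree", "species_tree.nwk"), "w") as fh:
        fh.write(write_tree(tree) + "\n")
    triads = extract_triads(tree)
    with open(p("triads", "triads.tsv"), "w") as fh:
        fh.write(triads_to_tsv(triads))

    # --- gene trees: MSC on the tree rescaled to coalescent units
    coal_scale = 4.0  # Ma per coalescent unit -> moderate discordance
    coal_tree = tree.clone(depth=1)
    for edge in coal_tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= coal_scale
    gene_trees = sim_msc_gene_trees(coal_tree, n_loci=200, seed=rng.getrandbits(31))
    support_rng = random.Random(rng.getrandbits(31))
    with open(p("gene_trees", "gene_trees.nwk"), "w") as fh:
        for gt in gene_trees:
            for node in gt.preorder_node_iter():
                if not node.is_leaf() and node.parent_node is not None:
                    node.label = str(support_rng.randint(60, 100))
            fh.write(write_tree(gt) + "\n")

    # --- quartet data for every triad, alternating no-admixture and
    # admixed histories
    freq_dir = os.path.join(out_dir, "freqs")
    os.makedirs(freq_dir, exist_ok=True)
    paths["freq_dir"] = freq_dir
    for i, triad in enumerate(triads):
        internode_cu = max(triad.internode / coal_scale, 0.05)
        t2 = max(triad.sister_age / coal_scale, 0.2)
        cfg = QuartetSimConfig(
            t2=t2,
            t1=t2 + internode_cu,
            t_out=t2 + internode_cu + 2.0,
            theta=3.0,
            gamma=0.0 if i % 2 == 0 else 0.3,
            n_loci=600,
            seed=rng.getrandbits(31),
        )
        m = sim_quartet_freqs(cfg)
        m.to_tsv(os.path.join(freq_dir, f"{triad.triad_id}.tsv"))

    # --- equal-area grid, ranges, climate rasters
    nrows = ncols = 12
    spacing_km = 200.0
    lat0, lon0 = 10.0, -75.0  # grid origin (top-left), roughly Neotropical
    deg_per_cell = spacing_km / 111.0
    grid_rows = []
    for r in range(nrows):
        for c in range(ncols):
            grid_rows.append(
                {
                    "cell_id": f"c{r}_{c}",
                    "lat": round(lat0 - r * deg_per_cell, 6),
                    "lon": round(lon0 + c * deg_per_cell, 6),
                    "area_km2": spacing_km**2,
                }
            )
    pd.DataFrame(grid_rows).to_csv(p("grid", "grid.tsv"), sep="\t", index=False)

    range_rows = []
    species = sorted(l.taxon.label for l in tree.leaf_node_iter())
    for sp in species:
        for r, c in sorted(_block_range(rng, nrows, ncols)):
            range_rows.append({"species": sp, "cell_id": f"c{r}_{c}"})
    pd.DataFrame(range_rows).to_csv(p("ranges", "ranges.tsv"), sep="\t", index=False)

    clim_rng = np.random.default_rng(rng.getrandbits(31))
    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    t_present = 26.0 - 0.4 * rr + 0.15 * cc + clim_rng.normal(0, 0.3, (nrows, ncols))
    t_lgm = t_present - (3.0 + clim_rng.normal(0, 0.8, (nrows, ncols)))
    write_esri_ascii(p("climate_present", "climate_present.asc"), t_present,
                     cellsize=deg_per_cell)
    write_esri_ascii(p("climate_lgm", "climate_lgm.asc"), t_lgm,
                     cellsize=deg_per_cell)

    # --- path model files: miniature variants of the default model set,
    # sized so they stay estimable on the bundle's handful of triads
    models_dir = os.path.join(out_dir, "models")
    os.makedirs(models_dir, exist_ok=True)
    paths["models_dir"] = models_dir
    mini_models = {
        "combined": [
            "log_geo_distance -> log_z_signal",
            "log_z_signal -> discordance",
            "log_internode -> discordance",
        ],
        "ils_only": [
            "log_internode -> discordance",
            "log_geo_distance",
            "log_z_signal",
        ],
        "introgression_only": [
            "log_geo_distance -> log_z_signal",
            "log_z_signal -> discordance",
            "log_internode",
        ],
    }
    for name, lines in mini_models.items():
        with open(os.path.join(models_dir, f"{name}.txt"), "w") as fh:
            fh.write("\n".join(lines) + "\n")

    # --- config
    config = f"""seed = {seed}

[paths]
species_tree = "species_tree.nwk"
gene_trees = "gene_trees.nwk"
triads = "triads.tsv"
freq_dir = "freqs"
ranges = "ranges.tsv"
grid = "grid.tsv"
climate_present = "climate_present.asc"
climate_lgm = "climate_lgm.asc"
models_dir = "models"

[parameters]
support_threshold = 80.0
subsample_sizes = [100, 250]
n_boot = 100
alpha = 0.05
grid_spacing_km = {spacing_km}
"""
    with open(p("config", "config.toml"), "w") as fh:
        fh.write(config)
    return paths
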