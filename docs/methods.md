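# Methods

This note records the models behind each stage, the defaults that matter,
the numerical choices, and what the synthetic-data generators do and do not
emulate.

## Trees

Trees are rooted dendropy trees read from Newick; numeric internal-node
labels are interpreted as support values (the IQ-TREE SH-aLRT convention).
Support-based collapsing contracts every internal non-root node whose
support is *strictly* below the threshold (default 80; a node at exactly 80
is kept), re-attaching children with their own branch lengths. Nodes with
no support value are never collapsed — absence of a label is not evidence
of low support.

Exclusive triads are internal nodes with exactly three descendant tips,
resolved as a cherry (P1, P2) plus a third tip P3. The outgroup is the tip
of the triad node's sister clade with the greatest assembly completeness;
completeness ties (including the no-table default, where all species tie)
break to the lexicographically smallest label so reruns are deterministic.
Three-tip polytomies are skipped with a warning rather than arbitrarily
resolved; a triad whose parent is the root (no tip-bearing sister) is
emitted with the outgroup flagged missing.

Node ages require ultrametricity within a relative tolerance of 1e-6 of
tree height; age = height − root distance. The Brownian covariance matrix
V has V[i,j] = root-to-MRCA path length and the root-to-tip distance on
the diagonal.

## Gene-tree discordance

Classification of a species-tree clade against one gene tree, after
restricting the clade to the taxa present in that gene tree (set S,
universe U = gene-tree tips):

- uninformative if |S| < 2 or U \ S is empty;
- concordant if the gene tree contains a clade with tip set exactly S;
- conflicting if any resolved gene-tree clade partially overlaps S
  (rooted clades are compatible iff nested or disjoint);
- uninformative otherwise (only polytomies stand in the way).

The discordance ratio divides conflicts by *resolved* trees only
(concordant + conflicting); a node where no gene tree is resolved has an
undefined (NaN) ratio and is excluded downstream.

The tip-level summary weights the ratios of a tip's subtending nodes by
2^−(j−1), j = 1 at the node immediately above the tip, renormalized over
the nodes that actually have a defined ratio (so adding undefined nodes
changes nothing). The weights are purely topological: node ratios are
plain proportions, not rates, so there is no branch-length term to
integrate — this is a deliberate design choice and the main place a
branch-length-weighted variant would differ; it is flagged for sensitivity
analysis rather than implemented as an option.

Geographic summaries reduce to unweighted means of tip values over
user-supplied species-to-grid-cell memberships; no map-projection machinery
is included.

## The D-statistic

Sites are polarized against the outgroup: the ancestral allele is the
outgroup's major allele; sites with an exact 50/50 outgroup tie or any
taxon entirely missing are dropped (counted, not imputed). Per site,

    abba = (1 − p1) p2 p3 (1 − p4),    baba = p1 (1 − p2) p3 (1 − p4),

and D = (Σabba − Σbaba)/(Σabba + Σbaba). A site is *informative* when
abba + baba > 0, which for fixed sites reduces to the strict ABBA/BABA
patterns. Subsampling to 100/250/500 informative sites is uniform without
replacement with an explicit seed; triads with fewer informative sites than
requested are dropped and reported, not silently skipped.

Significance: the resampling unit is the **locus**. Each of the (default
100) bootstrap replicates draws loci with replacement up to the original
locus count, with per-locus ABBA/BABA sums precomputed, and recomputes D.
Z = D / SD(replicates), p = 2(1 − Φ(|Z|)). The bootstrap runs over the loci
represented in the *selected* site set (resampling after subsampling). A
bootstrap SD of exactly zero flags Z and p undefined; one locus is a hard
error. The normal reference for Z was checked against the worked
Z = 3.895 → p = 9.8e-5 conversion.

## Predictors

Ranges are sets of equal-area grid cells (a gridded approximation of
polygon range maps: the analysis needs only distances, areas, overlaps and
centroids, all of which grids make exactly testable). Distance between two
ranges is 0 when the cell sets intersect, else the minimum haversine
distance between cell centroids (Earth radius 6371 km) — an approximation
to edge-to-edge distance at the grid's resolution. Climate-change velocity
per cell is |T_present − T_LGM| / 21,000 yr divided by the Euclidean norm
of the spatial gradient of present temperature (central differences,
one-sided at edges), with gradients capped below at 1e-6 °C/km to avoid
division blow-up in flat fields; the velocity for a species pair is the
mean over the union of the two ranges' cells. Velocity is invariant to
adding a constant to both epochs.

Transformations before modeling: absolute values for latitude, climate
velocity and the Z-score, then natural logs of everything except the
discordance ratio; geographic distance is logged as ln(km + 1) so sympatric
pairs (0 km) map to 0. The introgression signal entering the models is |Z|
(a signed Z cannot be logged); the binary coding is 1 iff the two-sided p
is below α = 0.05. Rows with a nonpositive value where a log is required
are dropped with a reason rather than patched.

## Path analysis

For a DAG over the predictor columns, the d-separation basis set contains
one claim per non-adjacent pair (x, y): x ⊥ y | pa(x) ∪ pa(y) (the pair
itself excluded). The regression response is the pair member later in the
causal (topological) order, so colliders never condition on themselves;
claim order is deterministic (topological, then lexicographic). Each claim
is tested by GLS with covariance proportional to the Brownian matrix V of
the triad-level tree (each triad represented by one constituent tip), and
the claim p-value is the two-sided t-test on x's coefficient with
df = n − parameters. Singular designs raise an error naming the collinear
columns; basis p-values of exactly zero are clamped to the smallest
positive float before the log.

Fisher's C = −2 Σ ln p is referred to χ² with 2k df; a saturated model has
k = 0, C = 0, p = 1. Models are ranked by CICc = C + 2qn/(n − 1 − q) with
**q = number of edges + one intercept per endogenous variable**; the
convention is written into the run manifest because CICc comparisons are
convention-sensitive (they are internally consistent here). Ties break by
fewer parameters, then name. Coefficients are PGLS fits of each endogenous
variable on its parents, standardized by the GLS-scaled standard deviations
of source and target (SD-standardization, not range-standardization).

Only Brownian-motion correlation is implemented — no Pagel's λ or OU
transform. The binary-introgression variant is fitted with the same
Gaussian PGLS on the 0/1 indicator, i.e. a linear-probability
approximation; a phylogenetic logistic regression is out of scope.

## Synthetic data

`sim_msc_gene_trees` runs the standard multispecies coalescent, one haploid
lineage per species, with exponential within-branch coalescence (rate =
number of pairs) in coalescent units. It was validated against the closed
form P(discordance) = (2/3)e^−t at the sister node of a pectinate quartet
and cross-checked against msprime on the same four-population history.

`sim_quartet_freqs` simulates the pectinate quartet ((P1,P2),P3),O with
splits at t2 < t1 < t_out (defaults 1, 2, 4 coalescent units). Admixture is
a per-locus pulse: with probability γ the recipient lineage (P2 by default)
is reassigned to the P3 population at a contact time inside (0, t2)
(default t2/2). Mutations are Poisson(θ × genealogy length), θ = 3 per
locus by default (chosen to give a few hundred informative sites per
500-locus dataset, the order of the empirical per-triad yields), placed
uniformly on branches under infinite sites; each yields one 0/1 site
pattern. Not emulated: diploid genotypes (one haploid lineage per taxon
matches the effective information of one sampled individual per species),
recombination within loci, sequencing error, demographic size change, and
ongoing migration (the pulse is the minimal model producing the ABBA
excess the test targets). Passing tests therefore demonstrate statistical
correctness of the estimator under clean coalescent data, not robustness
to those real-data complications.

`sim_traits_on_tree` draws exogenous variables as unit-rate Brownian motion
on the tree and endogenous ones as coefficient-weighted parent sums plus
Brownian residuals of stated SD — a linear SEM with phylogenetically
correlated errors, matching the assumptions of the PGLS d-separation tests.

`make_fixture_bundle` writes a self-consistent miniature study: a 40-tip
dated tree (height 20 Ma) with at least ten exclusive triads, 200 MSC gene
trees (1 coalescent unit = 4 Ma, giving moderate discordance) with random
supports in 60–100, quartet data for every triad (600 loci, alternating
γ = 0 and γ = 0.3), a 12×12 equal-area grid (200 km spacing) with
block-shaped ranges and smooth present/LGM temperature rasters, and
miniature versions of the three shipped path models sized to stay
estimable on a handful of triads. All of it is a pure function of the seed.

## Problem sizes used in validation

The statistical checks run at: 500 null coalescent datasets (500 loci) for
D-statistic calibration; 200 datasets at γ = 0.3 for power; 150 datasets at
γ = 0.1 for the subsample-size trend; 2,000 loci per branch length for the
(2/3)e^−t comparison; 1,000 random tree pairs for classifier-vs-oracle
agreement; and 150–300 SEM replicates at n = 130 triads (the primary
empirical sample size) for path-analysis calibration. These sizes give
Monte-Carlo standard errors comfortably inside the asserted tolerances.

## Known limitations

- The D-statistic cannot detect sister-pair introgression by construction,
  and strong ancestral population structure can mimic gene flow; the
  implementation inherits both properties of the statistic itself.
- The concordance classifier is binary and stringent (a single misplaced
  tip is conflict), so absolute discordance levels depend on gene-tree
  estimation quality upstream.
- Range geometry is only as fine as the grid; edge-to-edge distances are
  centroid-to-centroid at cell resolution.
- CICc values are comparable only within a run (same q convention, same
  rows); the ranking, not the absolute value, is the product.
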