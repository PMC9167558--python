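# Methods

`invashift` quantifies how the gut microbiome of invasive herbivorous fishes
(the rabbitfishes *Siganus rivulatus* and *S. luridus*, which entered the
Mediterranean through the Suez Canal) changes between the native range (Red
Sea) and invaded regions (Levantine Sea, Northern Crete).  The pipeline
covers table-level cleaning, Hill-number diversity, core-microbiome
identification, multivariate testing, differential abundance, functional
(SCFA) beta analysis, and the within/between-species homogenization
summaries, with a synthetic-data generator providing planted ground truth
for every stage.

## Diversity model

Diversity is expressed as Hill numbers (effective numbers of taxa or
lineages) of order *q*.  For a relative-abundance vector *p*:

- `hill_alpha(p, 0)` is richness (support size);
- `hill_alpha(p, 1) = exp(−Σ p_i ln p_i)` (exponential of Shannon entropy);
- general `q ≠ 1`: `(Σ p_i^q)^{1/(1−q)}`, evaluated on the support.

The phylogenetic facet replaces taxa by tree branches: branch *b* with
length `L_b` carries abundance `a_b` (summed leaf abundances below it), and
diversity is computed over units weighted by `L_b / T` with mean depth
`T = Σ L_b a_b`.  On a star tree with unit branch lengths this equals the
taxonomic Hill number exactly, which is the main internal consistency check.
`q = 1` is always evaluated by its closed-form limit, never by approaching
`q → 1` numerically.

Pairwise beta diversity uses the two-community partitioning with equal
pooling weights (1/2, 1/2), giving `beta = gamma / alpha ∈ [1, 2]`.  The
reported dissimilarity is the Sørensen-type local overlap complement
`1 − C_qN` with `N = 2`, chosen because it reduces to classic Sørensen
dissimilarity at `q = 0` (presence–absence) and to `ln(beta)/ln 2` at
`q = 1` (where it equals the Jensen–Shannon divergence over ln 2 for the
taxonomic facet).  The Jaccard-type `1 − U_qN` is exposed as
`variant="jaccard"` because the literature uses both normalizations and the
choice is not always reported.  For the phylogenetic facet the tree is by
default pruned to the union support of each pair and `T` recomputed
(framework-consistent); a fixed-`T` mode (`prune=False`) reuses one global
branch decomposition and is much faster on large sample sets.

Default index configurations: `q ∈ {0, 1}` × taxonomic facet at Phylum,
Family and ASV ranks, plus `q ∈ {0, 1}` × phylogenetic facet at the ASV
rank — eight in total.  Phylogenetic diversity is leaf-level, so it is not
computed at collapsed ranks unless the caller supplies a rank-collapsed
tree.

## Core microbiome

A taxon whose `N` total reads were scattered at random over `n` comparable
samples would have Poisson(λ = N/n) counts per sample and expected occupancy
`n (1 − e^{−λ})`.  The default core rule (`at_expectation`) calls a taxon
core when its observed occupancy is at or above this expectation (and at
least `min_occupancy = 1`); an `envelope` mode instead compares against the
lower α-quantile of simulated Poisson occupancies, as a more permissive
sensitivity analysis.  The published description of the source algorithm is
ambiguous about the exact decision rule; "occupancy at or above the random
expectation" is the minimal reading and is the default.

Unequal group sizes are handled by the bootstrap consensus: `B = 1000`
subsamples of fixed size `n_boot` (the smallest per-region group for each
species) are drawn without replacement, the Poisson rule is applied to each,
and a taxon joins the consensus core when called in > 80% of iterations in
at least one (species, region) group.  Counts are used as given; rarefied or
equal-depth input is recommended because the Poisson null assumes uniform
sampling effort (documented, not enforced).

## Multivariate tests

PERMANOVA uses the McArdle–Anderson trace formulation on the Gower-centered
matrix of `−d²/2` with sequential (Type-I) sums of squares in the order
Region, Season, Region:Season (configurable).  Pseudo-F for every term uses
the full-model residual mean square.  P-values come from free permutation of
sample labels, `(1 + #{F* ≥ F}) / (1 + m)`, so they are never zero; for
`n ≤ 9` an exhaustive enumeration mode replaces Monte-Carlo permutations.
Pairwise PERMANOVA runs the one-way test on every pair of factor levels with
optional Benjamini–Hochberg adjustment across pairs.

PERMDISP embeds the distance matrix by PCoA *keeping* negative-eigenvalue
axes and measures each sample's distance to its group center as
`sqrt(max(0, d²_real − d²_imaginary))` (the standard correction for
non-Euclidean dissimilarities).  The F statistic is a one-way ANOVA on these
distances; its p-value permutes the distances across groups.  The center
defaults to the centroid; a spatial-median option (Weiszfeld iteration in
the corrected geometry) is provided because reference implementations differ
in their default.

## Differential abundance

Two routes are always emitted: one-way ANOVA on centered log-ratio (CLR)
transformed counts (pseudocount 0.5 added before the transform; rows sum to
zero by construction), and Kruskal–Wallis with tie correction on relative
abundances, BH-adjusted across the features of one rank (one rank × one
feature kind = one correction family).  Both raw and FDR-adjusted
significance flags are reported because summary percentages in the
literature are sometimes quoted on raw p-values.  Features constant across
all samples are flagged degenerate with `p = 1` by convention.

## Homogenization and trajectory labels

Pairwise dissimilarities are collected in three contexts: conspecific pairs
within one region, conspecific pairs across two regions, and heterospecific
pairs within one region.  Percent homogenization from the native region to a
comparison region is `100 (mean_ref − mean_cmp) / mean_ref`, reported as the
unweighted mean ± SD across the configured diversity indices, with the
per-configuration table always emitted.  Rank tests (two-group
Kruskal–Wallis, or Mann–Whitney rank-sum for the two-species contrast) are
applied to the raw collections of pairwise values; these values share
individuals and are not independent, so every test result carries an
explicit pseudoreplication caveat rather than an invented correction.

Trajectory labels: per species, the variability verdict compares
within-region dissimilarity between ranges (sign + rank test at α = 0.05 →
homogenization / differentiation / no_change); the shift verdict flags
species whose between-region pairs exceed their pooled within-region pairs;
the interspecific verdict compares heterospecific dissimilarity across the
two co-occurrence regions.  When both species homogenize and the
interspecific dissimilarity drops, the overall label is "homogenization
within and between species".

## SCFA functional analysis

KO (KEGG Orthology) tables are treated exactly like taxa tables.  Each
short-chain fatty-acid group (formate 25 KOs, acetate 17, propionate 13,
butyrate 17, valerate 14, plus their union) selects a KO subset which is
re-closed to relative abundance — each group is analysed as its own
composition — before the Hill / PERMANOVA / PERMDISP / homogenization
machinery runs.  The actual KO identifiers per group are not public, so the
shipped defaults are synthetic placeholder ids with the published
cardinalities; a TSV mapping (`group`, `ko_id`) replaces them for real data.

## Synthetic data generator

The generator is a Dirichlet-multinomial community model.  Each (species,
region) group has a mean profile `π_g` and concentration `θ_g`; individuals
draw compositions `Dirichlet(θ_g π_g)` and counts
`Multinomial(depth, ·)` with log-normal depths (mean 5000, σ_log 0.3,
floor 200).  Planted structure:

- **Core taxa** (10% of 150 features, 60% of the mean profile mass) receive
  equal shares and are carried by every individual.  Non-core taxa are
  patchy: each has a carriage probability drawn once from U(0.5, 0.95) and
  is present in a random subset of individuals.  This occupancy–abundance
  contrast is what makes the planted core identifiable and mirrors real ASV
  tables, where only core taxa approach full occupancy.
- **Regional shifts**: 20% of features get a log-fold increase in invaded
  regions (1.0 in the Levantine, 1.5 in Crete, then re-closure), creating a
  gradient away from the native composition.  In addition the last third of
  the core block *decreases* (log-fold −1.0 / −1.5) in the invaded range:
  dominant core lineages fade in relative abundance while keeping full
  occupancy, which is what carries the regional signal into the KO table
  and mirrors the observed fading of the core along the invasion gradient.
- **Season**: a 0.3 log-fold bump on a small feature subset in autumn, so
  Region:Season interaction tests have signal.
- **θ defaults** were calibrated once with `theta_for_reduction` (bisection
  against the Monte-Carlo dispersion oracle) so the planted within-group
  dissimilarity decreases reproduce the observed invasion trajectory:
  ≈46% (Levantine) and ≈61% (Crete) for *S. rivulatus* and ≈29% for
  *S. luridus*, from a native θ = 40.
- **KO table**: a fixed sparse linear map (each KO fed by 5–20 taxa with
  weights in (0.2, 1]) applied to the taxa counts and rounded.

Default group sizes mirror the field design (*S. rivulatus*: 20 per
region × season over three regions; *S. luridus*: 8 per cell in Red Sea and
Crete only).  `expected_dispersion` gives the Monte-Carlo oracle (block mean
± SE) of within-group q = 1 taxonomic dissimilarity used for
parameter-recovery checks.

What the generator does **not** emulate: real sequences or real taxonomy
content (labels are arbitrary nested strings; the tree is a Yule tree over
feature ids), between-species differences in the mean profile (species
differ only in θ and sampling design, so interspecific dissimilarity
derives from dispersion, not from species-specific composition), overdispersed
per-feature count noise beyond the Dirichlet, and environmental
compartments (water/sediment/algae).  Passing tests therefore certify the
statistical machinery and its power under a plausible community model, not
performance on any particular real dataset.

## Numerical choices and edge cases

- Abundance vectors must sum to 1 within 1e−8; `0 ln 0 = 0` throughout.
- `beta` ratios are clipped to [1, 2] and dissimilarities to [0, 1] to
  absorb floating-point excursions at the boundaries.
- Distance matrices are validated symmetric to 1e−12 with zero diagonals
  and symmetrised before use.
- Permutation counts default to 999; every permutation p-value respects the
  `(1 + b)/(1 + m)` floor.  All stochastic stages take explicit seeds, and
  the pipeline derives per-stage seeds from one master seed so stages can be
  re-run in isolation with identical results.
- Rarefaction is a single multivariate-hypergeometric draw per sample
  (without replacement); samples under the depth are dropped and listed,
  never padded.
- At rank aggregation, features unassigned at the target rank are pooled
  per distinct upstream label path, so unassigned lineages under different
  phyla are not merged.
- The host-only dataset is analysed unrarefied by default (rarefaction is a
  flag), matching the study design choice of keeping all information for
  core and functional analyses.

## Problem sizes used in checks

The packaged test-suite and the reproduction script run on simulated
datasets of 100–160 samples and 40–150 features, with 199–999 permutations,
B = 200–1000 bootstrap iterations, and 20 replicates for parameter-recovery
checks — sizes at which the Monte-Carlo error of every reported quantity is
small relative to the tolerances being checked.

## Known limitations

- The Poisson core rule degenerates for taxa observed in *every* sample:
  `O_exp < n` always, so full-occupancy taxa are called core regardless of
  abundance pattern.  This is a property of the published approach, not a
  bug; the bootstrap consensus attenuates borderline cases.
- The homogenization rank tests are descriptive (pseudoreplication caveat
  above).
- BIOM support covers the JSON (1.0) encoding, dense or sparse; HDF5-based
  BIOM 2.x files should be exported to JSON or TSV first.
- Phylogenetic beta with per-pair pruning scales as O(pairs × tree size);
  use `prune=False` for large sample sets.
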