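# Methods

`mycospat` implements a complete analysis chain for asking whether the
root-associated fungal communities of co-occurring forest trees predict the
trees' spatial relationships, together with a synthetic forest generator that
makes the chain testable end to end at desk scale.

## Scientific model

The pipeline operates on four coupled objects:

1. a **stem map** — every individual of every focal species in a rectangular
   plot, with coordinates and DBH (diameter at breast height, cm);
2. **root-tip OTU tables** — per-sample fungal community profiles from roots
   of identified hosts, rarefied to a common read depth;
3. **bulk-soil OTU tables** — background fungal communities on a sampling
   grid, rarefied to their own depth;
4. per-species **covariates** — a phylogeny (newick), a trait table, and
   fungal guild annotations (ectomycorrhizal, plant pathogen, saprotroph).

### Spatial co-occurrence

For each species pair (i, j) the bivariate pair correlation function

g_ij(r) = Σ_{p∈i, q∈j} k_h(r − ‖p−q‖) · e(p,q) / (2πr λ_i λ_j |W|)

is estimated with an Epanechnikov kernel k_h (Stoyan's rule of thumb
h = 0.15/√λ̂ by default) and translation edge correction
e(p,q) = |W| / ((W_x − |Δx|)(W_y − |Δy|)). The pair summary T is the mean of
ĝ_ij over 0–30 m. A null distribution of T is built from toroidal shifts of
one pattern against the other (default 199 shifts); the pair is called
**aggregated** when T exceeds the upper α-quantile of the null, **segregated**
below the lower, and unclassified otherwise (α = 0.05).

### Community statistics

Bray–Curtis dissimilarities among rarefied samples feed pairwise PERMANOVA
(pseudo-F with a +1-corrected permutation p-value; exhaustive enumeration on
small designs), with Benjamini–Hochberg correction within each focal species.
A species whose root community differs significantly from **all** 38 others
is *host-specific*; from at least 90 % of them (⌈0.9·38⌉ = 35), 
*host-dependent*. Mantel tests relate community distance to phylogenetic
(cophenetic) and functional (Gower) distance. Core OTUs are those detected in
at least a cutoff fraction of a species' samples; cutoffs are compared as
exact rationals so 4-of-8 detection is core at 0.5.

### Modified relative abundance (MRA)

For a pair (A, B), core OTUs split into **shared** (core in both) and
**unique** (core in exactly one). With RA_X,i the mean relative abundance of
OTU i across host X's samples:

- shared side: MRA_i = RA_A,i · RA_B,i / Σ_shared RA_A,j · RA_B,j
- unique side: MRA_i = RA_owner,i / Σ_unique RA_owner,j

so each non-empty side sums to exactly 1. Worked example: shared RAs
A = (0.2, 0.1), B = (0.3, 0.4) give products (0.06, 0.04) and shared MRA
(0.6, 0.4). Per-guild MRA sums (pathogen/EcM/saprotroph) are contrasted
between aggregated and segregated pairs with Wilcoxon rank-sum tests
(effect size r = |Z|/√N, tie-corrected).

### Predicting co-occurrence from fungi

Each classified pair becomes one row of a feature table; candidate predictor
sets are scalar dissimilarities (relative abundance difference RA, phylogenetic
distance PL, functional-trait distance FT, fungal richness difference RICH,
community Bray–Curtis COMM) and the per-OTU MRA profiles (MRA-shared,
MRA-unique). A random forest (1000 trees) is trained on a stratified 80/20
split with random over/under-sampling to balanced classes; the observed AUC is
compared to a shuffled-label branch over 100 repetitions per predictor set
(Wilcoxon + FDR across sets; one-way ANOVA with Tukey HSD compact letters
across sets).

### Background soils

Bulk-soil variograms are fitted by weighted least squares (Matheron estimator,
weights N(h)/h², spherical or exponential families) and interpolated by
ordinary kriging (weights constrained to sum to 1, exact at data points with
zero nugget). For per-individual background communities the k = 3 nearest soil
samples are pooled (3 × 4100 = 12,300 reads at the default depths). Before
pairing roots with backgrounds, conspecifics are thinned so no two retained
individuals are within 30 m: trees are linked into <30 m proximity components
and one tree per component is kept uniformly at random.

## Synthetic forest generator

The generator emulates the *structure* of a subtropical 50-ha census
(1000 m × 500 m window), not any particular forest:

- **Stem maps** are Thomas cluster processes (default 25 parents/species,
  cluster σ = 12 m, 80 individuals/species). Pairs planted as *aggregated*
  share parent locations (transitively — parent sharing is resolved on
  connected components of the aggregation graph); pairs planted as
  *segregated* have parents rejection-sampled under a hard-core distance
  (default 60 m) against the other component's parents.
- **DBH** is lognormal(μ=1.5, σ=0.8); stages are sapling (≤5 cm),
  juvenile, adult (≥10 cm).
- **Environmental surfaces** are Gaussian random fields with a spherical
  covariance (range 150 m, sill 1) on a 25 m grid, so variogram-fitting can
  be checked against known truth.
- **OTU tables**: each host's community centroid is a Dirichlet draw whose
  concentration shrinks as `host_effect` grows (0 collapses all hosts onto
  one centroid — the null used for calibration tests); samples are
  multinomial draws rarefied to the root/soil depths (defaults 3000/4100).
- **Guild signal**: segregated pairs share an elevated plant-pathogen OTU;
  aggregated pairs each get an elevated ectomycorrhizal OTU of their own
  *plus* one jointly elevated unassigned OTU. The joint OTU balances the
  pairwise community overlap of aggregated pairs against the shared pathogen
  of segregated pairs, and total boost mass is equalized across species with
  unassigned fillers — so the planted contrast lives in guild identity and
  per-OTU MRA structure, not in bulk community distance. Without this
  balancing, a community-dissimilarity scalar predicts the planted classes
  trivially, which would misrepresent what the MRA features add.
- `planted_demo_config()` builds a 15-species demonstration forest: two
  parent-sharing groups of 6 (30 aggregated pairs) plus 3 independent
  species, each grouped species segregated from one independent (12
  segregated pairs).

### What the generator does not emulate

No topography, habitat association, or dispersal limitation beyond
clustering; no phylogenetic signal in the fungal communities (the demo
phylogeny and traits are random, so PL/FT predictors are uninformative by
construction); no sequencing-error or chimera model; read depths and OTU
richness are far below field scale.

## Numerical choices

- All stochastic stages draw from `numpy` `SeedSequence` substreams of one
  master seed; pipeline reruns are byte-identical.
- Rarefaction uses the multivariate hypergeometric distribution (subsampling
  without replacement), not multinomial resampling.
- PERMANOVA/Mantel switch to exhaustive enumeration when asked, enumerating
  distinct group assignments (or all row permutations) exactly; permutation
  p-values are +1-corrected, so under the null p is discrete-uniform and
  P(p ≤ α) = α exactly.
- Kriging solves one LU factorization per system and averages duplicate data
  locations (with a warning) to keep the system nonsingular.
- Class balancing resamples both classes to the mean class size (round half
  to even); the validation fold is split off before any balancing or label
  shuffling.
- The test suite scales down Monte-Carlo sizes for CI budgets (99 toroidal
  shifts instead of 199; 8–10 model repetitions at 150–300 trees instead of
  100 × 1000) while `scripts/acceptance.py` keeps the full 100 × 1000
  setting for the shuffled-AUC target. These are runtime choices, fixed
  before the corresponding checks were frozen.

## Limitations

Desk-scale defaults (hundreds of individuals, hundreds of OTUs, thousands of
reads) are one to two orders of magnitude below a real 50-ha census; absolute
AUCs, significance counts, and host-specificity tallies from the synthetic
demo are not comparable to field values. The toroidal-shift null conditions
on each pattern's own clustering but assumes stationarity; strongly
inhomogeneous patterns would need an inhomogeneous pcf, which is out of
scope.
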