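# Methods

## The synthetic cohort model

Downstream methods are exercised on synthetic cohorts whose generative
model mirrors the structure the analysis assumes, not any particular
dataset.

**Counts.** OTU counts are Dirichlet-multinomial. A shared base
concentration vector over genera is drawn log-normally (σ = 1.2) and
scaled to a total concentration of 60, which sets the compositional
overdispersion; each genus splits its concentration over its OTUs with a
Dirichlet(2) weight vector shared by both communities. Community types
differ in two ways: `n_discriminant_genera` (default 30) genera have
their concentration multiplied by `exp(effect_size)` in one community
(alternating direction, default effect 2.0), and `n_exclusive_genera`
(default 6) genera are zeroed in one community (alternating, or all in
one community via `exclusive_absent_from`, which also makes that
community the sparser one). Per-sample depth is log-normal; the default
mean depth is 5,000 reads — a desk-scale stand-in for the ~59,000-read
scale of real 16S libraries that keeps simulations cheap without
changing what the tests measure.

**Phylogeny.** Trees are rooted, binary, with exponential(0.1) + 0.01
branch lengths. In cohorts each genus owns a contiguous clade of tips,
so genus-level abundance shifts are visible to UniFrac; `generate_tree`
alone produces an unconstrained random topology.

**Covariates.** Host variables (age, sex, breed, travel, telomere
proxy) are community-independent by default. Race elimination is
Bernoulli(0.33) in community 1 vs Bernoulli(0.16) in community 2. Diet
intakes (protein, fiber, ash, forage, energy units) are normal with
higher means in community 2. SCFA proportions are Dirichlet with
community 1 skewed toward acetate and community 2 toward propionate and
butyrate. Metabolite bins are exp(low-rank Gaussian structure + noise),
with four designated bins (alanine/valine/choline/isoleucine proxies)
shifted upward in community 1. All of these are configurable through
`metadata_effects`; every draw flows from one `numpy` Generator seeded
by `SyntheticConfig.seed`, so identical configs give bit-identical
cohorts.

**What the generator does not emulate:** read-level error, chimeras,
singleton inflation, phylogenetic signal in which genera are
discriminant, pedigree/kinship structure, and real compositional
covariance between diet and microbiota (diet shifts are drawn
independently of the counts given the community label). Passing
recovery tests therefore show the pipeline detects the *kind* of
structure the design posits at realistic sizes and noise — not that it
would reproduce any particular cohort's genus identities.

## Community typing

Distances: Bray-Curtis and Euclidean via `scipy.spatial.distance`;
UniFrac computed from a branch-by-tip incidence decomposition, with
branch abundance accumulated post-order and the root's own branch
excluded. Weighted UniFrac is normalized by Σ bᵢ(Aᵢ+Bᵢ) by default
(exposed as a flag, since either convention is common). PCoA is Gower
double-centering plus eigendecomposition; negative eigenvalues are
reported but not corrected (no Cailliez/Lingoes), and axes are limited
to positive eigenvalues. NMDS minimizes Kruskal stress-1 via SMACOF
with isotonic regression (scikit-learn), default k = 2, 20 restarts,
300 iterations, tolerance 1e-7.

PAM is classic BUILD + SWAP on the precomputed distance matrix. Swaps
are accepted only on strict cost decrease, and equal-cost candidates are
resolved by lowest index, making the procedure deterministic in the
distance matrix alone. K is chosen over 2..k_max (default 10) by the
maximum silhouette coefficient; SC > 0.5 is flagged as "reasonable
structure". Per-sample silhouettes follow the standard definition with
s = 0 for singleton clusters. Partition agreement is counted after
optimal (Hungarian) label matching; cross-distance concordance reports
pairwise adjusted Rand indices plus an exact-match flag.

The deletion-robustness procedure removes the k top-ranked genera
(PLS-DA loading ranks), re-normalizes each sample's composition,
recomputes Bray-Curtis and re-runs PAM at the reference K (K is held
fixed rather than re-selected; re-selection would conflate cluster-count
instability with membership instability). Misclassification is counted
after Hungarian matching.

## Discriminant genera

Univariate screening runs Fisher's exact test on presence/absence and
Mann-Whitney on relative abundances, BH-adjusted separately per test
family; a genus is significant when **either** adjusted p < α. The
either-rule is the permissive reading of "both tests combined"; the
conservative alternative (require both) is recoverable from the reported
per-test q-values. Log fold changes use community means with a 1e-6
pseudo-abundance so exclusive genera stay finite; exclusivity is flagged
explicitly. Mann-Whitney uses exact enumeration for tie-free pooled
samples of ≤ 20, otherwise the normal approximation with tie and
continuity corrections.

PLS-DA is NIPALS against the one-hot class matrix with deflation,
default 2 components and unit-variance scaling; genera are ranked by
their maximum absolute loading weight across components. The sparse
variant soft-thresholds each component's weight vector to a fixed genus
count (mixOmics-style); the cross-validation wrapper scores each
sparsity level by stratified-CV ROC-AUC and returns the smallest set
within 0.01 of the best AUC. Sparse k-means alternates k-means on
weight-scaled standardized features with weight updates maximizing the
weighted between-cluster sum of squares under ‖w‖₂ ≤ 1, ‖w‖₁ ≤ s, w ≥ 0
(soft-thresholding with bisection on the threshold). Because a
uniform-weight start can lock onto a noise partition when few features
are informative, the procedure restarts from random sparse weight
vectors (10 by default, the first uniform) and keeps the run with the
best objective; restarts are deterministic given the seed.

## Networks

Correlations are Pearson on relative abundances — compositional closure
induces spurious negative correlation, which is documented rather than
transformed away; PCIT is the mitigation used. PCIT visits every trio,
computes the three first-order partials, sets the trio tolerance to the
mean partial-to-direct ratio, and removes an edge if **any** third genus
explains it (both comparisons at or below tolerance). Trios containing
a perfect correlation, or where any partial/ratio is undefined, are
skipped. Edges additionally require |r| ≥ 0.35 and a two-sided
correlation t-test p ≤ 0.05 (no multiplicity correction — the plain
cutoff is deliberate), with |r| ≥ 0.60 marked strong; genera under 0.1%
mean relative abundance are excluded before anything else. Note that on
independent noise PCIT removes almost nothing — a null edge is rarely
jointly explained by a third variable — so the null edge rate is
essentially the tail probability of the r/p thresholds (~3.6% of pairs
at n = 36). Topology: degree, normalized shortest-path betweenness and
local clustering via networkx; the scale-free R² is the squared
correlation of log frequency vs log degree over observed degrees ≥ 1.

## Associations

PERMANOVA partitions the Gower-centered −D²/2 matrix with hat-matrix
projections; multi-term designs use sequential (Type I) sums of squares
in the order given, matching adonis2 semantics, and p-values permute
sample identities with the add-one rule (so p ≥ 1/(n_perm+1)). envfit
fits each variable onto the ordination axes by least squares (r²,
normalized direction) with the variable permuted for significance and BH
across variables. Two-way ANOVA uses Type II sums of squares on the
additive model via statsmodels (suited to unbalanced community × race
distance designs). Spectral bins are normalized by the probabilistic
quotient method against the median spectrum. Univariate screening
pairwise-deletes missing values (never imputes), tests continuous
variables by Mann-Whitney and categorical ones by Fisher exact
(Freeman-Halton enumeration for small 2×c tables, Monte-Carlo with 1e5
draws otherwise), and BH-adjusts within declared variable families.
Both the 0.05 and any looser reporting threshold are parameters.

## Power analysis

Power is estimated by Monte-Carlo simulation at a fixed community split
(default 15/51). Fisher: binomial success counts per community, two-
sided Fisher exact at α = 0.05; p-values are cached per unique count
pair. Mann-Whitney: group values drawn from uniform distributions
matched to the target mean and SD (support mean ± √3·SD — the skew
construction of the original description is not recoverable, so a
symmetric uniform with an optional floor truncation is used), tested
with the tie-free normal approximation, vectorized across replicates.
Required-n searches evaluate a strictly increasing grid with common
random numbers (one seed for every n, keeping curves monotone) and
bisect between the bracketing grid points; a `resolution` parameter
controls the bisection granularity (250 individuals for the desk-scale
age search, where Monte-Carlo noise makes unit resolution meaningless).
Effect-size curves scale Fisher proportions away from the pooled
proportion, p' = p̄ + m(p−p̄) clipped to [0,1], and Mann-Whitney mean
ratios around 1. Reported numbers use 10,000 reps (3,000 for the large-n
age search); calibration checks run at 500 replicates.

## Numerical conventions and limitations

- Pielou's evenness is reported as missing (NaN) when only one taxon is
  observed (0/0); rarity sums taxa below 0.2% relative abundance by
  default (the threshold is configurable — no canonical value exists).
- Core microbiota defaults: detection 1e-5, prevalence 0.999, both
  explicit parameters (prevalence conventions vary between 99% and
  99.9% in practice).
- Rarefaction is true subsampling without replacement (multivariate
  hypergeometric), dropping samples below the requested depth.
- BH adjustment is monotone and dominates the raw p-values but is not
  idempotent; q-values are reported alongside raw p-values throughout.
- PAM is exact BUILD + SWAP, O(K(n−K)·nK) per sweep — intended for
  cohort-scale n (tens to a few hundred samples), not thousands.
- The package does not attempt compositional data transforms (CLR),
  Dirichlet-multinomial mixture enterotyping, or analytic power
  formulas; these are out of scope by design.
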