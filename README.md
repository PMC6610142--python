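# enterokit

Community typing and downstream statistics for gut-microbiome cohorts,
built around the analysis of an endurance-horse 16S study design: a small
cohort (~50 animals) whose fecal microbiota partitions into two latent
community types ("enterotypes") that differ in diversity, discriminant
genera, fermentation products and diet — but not in host variables such
as age, sex or breed.

The package is aimed at microbiome analysts who want the full downstream
chain as tested, reusable functions, exercisable end-to-end on synthetic
cohorts with no data download:

- **Synthetic cohorts** (`enterokit.synthetic`): Dirichlet-multinomial
  OTU counts on a simulated phylogeny with two community types, genus
  clades, community-linked diet/SCFA/metabolite shifts and
  community-independent host variables.
- **Alpha diversity** (`enterokit.diversity`): rarefaction (multivariate
  hypergeometric), Chao1 = S_obs + F₁(F₁−1)/(2(F₂+1)), Shannon H,
  Pielou J = H/ln S, dominance, rarity, core microbiota.
- **Beta diversity and ordination** (`enterokit.beta`): Bray-Curtis,
  weighted/unweighted UniFrac from a branch–tip incidence decomposition,
  PCoA (Gower double-centering) and NMDS (Kruskal stress-1).
- **Community typing** (`enterokit.cluster`): PAM (BUILD + SWAP) on any
  distance, K selected by the maximum silhouette coefficient (SC > 0.5 =
  reasonable structure), cross-distance concordance and the top-k
  genus-deletion robustness procedure.
- **Discriminant genera** (`enterokit.discriminant`): Mann-Whitney +
  Fisher screening with BH correction, PLS-DA (NIPALS) loading ranks,
  sparse PLS-DA under cross-validated ROC-AUC, sparse k-means with
  lasso-constrained feature weights.
- **Co-occurrence networks** (`enterokit.networks`): PCIT partial-
  correlation filtering, |r| ≥ 0.35 and p ≤ 0.05 edge thresholds, node
  topology (degree, betweenness, clustering) and scale-free R².
- **Associations** (`enterokit.association`): PERMANOVA (sequential
  Type I SS, adonis2-style), envfit vector fitting with permutation
  p-values, two-way Type II ANOVA, probabilistic-quotient normalization
  of NMR-style spectra, univariate screening with per-family BH.
- **Power analysis** (`enterokit.power`): Monte-Carlo power of Fisher
  exact and Mann-Whitney community-type associations versus sample size
  (preserving the observed 15/36 community split) or versus effect size,
  with required-n search by grid + bisection.

## Worked example

```python
import enterokit as ek
from enterokit.cluster import select_k, label_agreement
from enterokit.discriminant import differential_genera, sparse_plsda_cv
from enterokit.power import power_fisher, required_n

cohort = ek.generate_cohort(ek.SyntheticConfig(seed=1))
rel = ek.to_relative_abundance(cohort.otu_table)
dm = ek.beta.unifrac_matrix(cohort.tree, rel, weighted=True)
types = select_k(dm, k_max=10)
print(f"K = {types.k}, silhouette coefficient = {types.silhouette_coefficient:.3f}")
print(f"agreement with simulated truth = {label_agreement(cohort.true_labels, types.labels):.2f}")

genus = ek.to_relative_abundance(cohort.otu_table.genus_table())
res = differential_genera(genus, types.labels)
sel = sparse_plsda_cv(genus, types.labels, seed=0)
print(f"significant genera: {len(res.significant)} of {genus.shape[1]}")
print(f"sparse PLS-DA: {len(sel.selected)} genera, CV AUC = {sel.cv_auc:.3f}")

req = required_n(lambda n, reps, seed: power_fisher(n, 15/51, 0.33, 0.16,
                                                    reps=reps, seed=seed),
                 target_power=0.9, n_grid=(100, 200, 300, 400, 600),
                 reps=10_000, seed=1)
print(f"required n for elimination difference (power 0.9): {req.n}")
```

prints

```
K = 2, silhouette coefficient = 0.636
agreement with simulated truth = 1.00
significant genera: 37 of 60
sparse PLS-DA: 2 genera, CV AUC = 1.000
required n for elimination difference (power 0.9): 325
```

Read: PAM on weighted UniFrac finds exactly the two simulated community
types with a silhouette well above the 0.5 "reasonable structure" bar;
univariate screening flags the shifted/exclusive genera; a couple of
genera already separate the communities perfectly under cross-validated
sparse PLS-DA; and detecting an elimination-rate difference of 33% vs
16% between communities at power 0.9 would need a cohort of roughly 325
animals — far above the 51 available.

The same pipeline is scriptable from a shell:

```bash
enterokit simulate --outdir run --seed 1
enterokit cluster --workdir run --distance weighted-unifrac
enterokit differential --workdir run
enterokit network --workdir run
enterokit power --test fisher --p1 0.33 --p2 0.16 --split 0.294 --target 0.9
```

## Documentation

`docs/methods.md` describes the generative model behind the synthetic
cohorts, each statistical procedure with its assumptions and defaults,
and the package's numerical conventions and known limitations.
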