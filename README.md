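# bearlink

Genotype–ecotype–phenotype linkage analysis for intensively managed
wildlife populations.

`bearlink` asks, for a population of individually monitored animals (the
motivating system is grizzly bears carrying GPS radiocollars and genotyped
at 15 microsatellites): do genetic structure and habitat-use structure
line up, and does either predict fitness proxies such as body mass, body
length and body condition?  It bundles the full analysis chain:

* **Genetic statistics** — allele frequencies, observed/expected
  heterozygosity, a Monte-Carlo Hardy–Weinberg exact test, homozygosity by
  loci (HL), Queller–Goodnight pairwise relatedness, allele-sharing
  molecular coancestry, and covariance PCA of genotypes.
* **Habitat use** — per-individual proportions of GPS fixes over seven
  land-cover classes, arcsine-square-root transform, habitat PCA,
  per-management-unit habitat availability with a χ² heterogeneity test,
  L1 availability distances and a neighbor-joining tree.
* **Clustering** — simulated-annealing K-means ecotypes (pseudo-F and
  spherical BIC for selecting k) and admixture-model Gibbs sampling of
  genetic clusters (Evanno ΔK, highest-Q hard assignment), plus the
  Pearson correlation between the two assignment vectors with a
  relabeling-sensitivity report.
* **Isolation by ecology (IBE)** — individual-based Mantel and partial
  Mantel permutation tests over genetic similarity *G*, geographic
  distance *D*, sex similarity *S* (F/F = 0, F/M = 0.5, M/M = 1) and
  ecological divergence *E*^PC1–3 (absolute differences of habitat PC
  scores).
* **Heterozygosity–fitness models (HFC)** — Bayesian hierarchical linear
  models with management-unit intercepts (and optionally unit-varying HL
  slopes),

      y_i     = x_i'β + α_u(i) (+ γ_u(i)·HL_i) + ε_i
      α_u     ~ N(μ_α, σ_α²),   γ_u ~ N(μ_γ, σ_γ²),   ε_i ~ N(0, σ²),

  fitted by a blocked Gibbs sampler with vague conjugate priors, compared
  by DIC, and checked with the Gelman–Rubin R̂ diagnostic and 95% credible
  intervals.
* **Translocation summaries** — cross-unit and northward event fractions
  and a unit-to-unit flow matrix for a management translocation record.
* **Synthetic data** — a generator with known ground truth: Balding–
  Nichols genotypes from K diverged subpopulations, Dirichlet habitat-use
  ecotypes coupled to the genetic clusters, phenotypes from the
  hierarchical model above, and a translocation event table.  Every
  analysis here is exercised and validated on these simulations.

## Worked example

```python
from bearlink.simulate import SimulationConfig, generate_genotypes, \
    generate_habitat_use, generate_phenotypes
from bearlink.genetics import heterozygosities, homozygosity_by_loci, \
    qg_relatedness
from bearlink.habitat import arcsine_sqrt, habitat_pca
from bearlink.cluster import sa_kmeans, admixture_gibbs, assignment_correlation
from bearlink.mantel import mantel, ecological_distance
from bearlink.hfc import HierarchicalHFCModel, ModelSpec

cfg = SimulationConfig(seed=42)          # 88 bears, 15 loci, 3 genetic
geno, truth = generate_genotypes(cfg)    # clusters, 2 ecotypes
use = generate_habitat_use(cfg, truth)
hl = homozygosity_by_loci(geno)
pheno = generate_phenotypes(cfg, truth, hl)

het = heterozygosities(geno)
print(f"mean Ho = {het.mean_ho:.2f}, mean He = {het.mean_he:.2f}")

eco = sa_kmeans(arcsine_sqrt(use), k=2, steps=20_000, restarts=5, seed=1)
gen = admixture_gibbs(geno, k=3, iterations=5000, seed=1)[0]
corr = assignment_correlation(eco.assignment, gen.assignment)
print(f"assignment r = {corr.r:.2f} (p = {corr.p:.3g}); "
      f"max |r| over relabelings = {corr.max_abs_r_over_relabelings:.2f}")

G = qg_relatedness(geno)
E1 = ecological_distance(habitat_pca(arcsine_sqrt(use)).scores, 1, geno.ids)
print(mantel(G, E1, n_perm=9999, seed=2).summary())

fit = HierarchicalHFCModel.from_dataframe(
    pheno, ModelSpec(response="log_mass", seed=3)).fit()
print(fit.summary())
```

prints

```
mean Ho = 0.67, mean He = 0.71
assignment r = 0.02 (p = 0.862); max |r| over relabelings = 0.44
Mantel: r = -0.095, one-sided p = 0.0004 (9999 permutations), 95% CI [-0.206, -0.003]
Hierarchical HFC model M2 (response: log_mass, n = 88)
DIC = -23.79 (Dbar = -35.63, pD = 11.85)   converged: True
parameter          mean     2.5%    97.5%   Rhat
sex               0.566    0.473    0.656  1.003 *
age               0.262    0.218    0.305  1.003 *
northing          0.222   -0.016    0.364  1.046
spring            0.089   -0.029    0.201  1.005
summer            0.158    0.061    0.258  1.002 *
hl                0.123    0.079    0.169  1.000 *
...
* 95% credible interval excludes 0
```

Reading the output: the simulated panel shows microsatellite-typical
diversity (observed heterozygosity 0.67).  The raw assignment correlation
is near zero *because cluster labels are arbitrary* — the sensitivity
report shows that a relabeling reaches r = 0.44, close to the planted
coupling.  The negative Mantel r between relatedness (a similarity) and
ecological divergence (a distance) means related individuals use similar
habitat — the IBE signature.  In the hierarchical model, males are heavier
(sex), mass grows with age, and homozygosity has a positive effect on
log-mass whose 95% credible interval excludes zero (the planted
heterozygosity–fitness correlation, on the standardised covariate scale).

A command-line pipeline wraps the same machinery:

```
bearlink simulate --seed 1 --out synthetic/
bearlink run --in synthetic/ --out results/ --seed 1
```

`results/` then holds one CSV per stage (diversity, relatedness and
coancestry matrices, cluster selection tables, the IBE Mantel battery, the
HFC model ranking with coefficient tables, habitat availability plus its
Newick NJ tree, the translocation flow matrix) and a `manifest.json`
recording every stage seed.

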