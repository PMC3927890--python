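# Methods

This note documents the statistical machinery implemented in `bearlink`,
the generating model behind its synthetic data, the numerical choices that
were genuinely open, and what the validation suite does and does not
establish about real data.

## The synthetic study system

No real genotype, telemetry or morphometric data ship with the package;
every analysis is exercised on simulations whose structure mirrors the
kind of intensively monitored bear population the pipeline targets: n = 88
individuals genotyped at 15 microsatellites with 8 possible alleles per
locus, three genetic subpopulations, two habitat-use ecotypes, and six
management units ordered south to north.

**Genotypes.** Divergence follows the Balding–Nichols construction:
ancestral allele frequencies p ~ Dirichlet(1, …, 1), subpopulation
frequencies ~ Dirichlet(p·(1−F)/F).  Under this model the expected
variance of a subpopulation frequency is F·p(1−p), so the single
parameter `fst` *is* the Weir–Cockerham θ the simulation should exhibit
(verified in the tests with an independent variance-components
estimator).  Individuals fill clusters in near-equal blocks; genotypes
are two independent draws from the cluster's frequencies.  The default
`fst = 0.10` produces visible but overlapping clusters, the regime in
which cluster-number selection is actually interesting.

**Ecotypes and habitat use.** Each ecotype is a Dirichlet distribution
over the seven land-cover classes (wetland, cutblock, shrub,
wetland-herbaceous, upland-herbaceous, barren, upland-forest).  The two
default profiles are a forest-dominated "montane" type (~64% upland
forest) and an open "alpine" type (barren/upland-herbaceous heavy); the
pooled sample is upland-forest dominated with wetland-herbaceous rare,
matching the ranking observed in collared bears.  An individual's ecotype
equals its genetic cluster, folded onto 1..k_eco by a monotone block map,
with probability `coupling` (default 0.6), and is uniform over all
ecotypes otherwise.  Two notes on this design:

* the fold is monotone ((c−1)·k_eco ÷ k_gen + 1, the identity when the
  counts match) rather than a modulo fold: a modulo fold of three
  clusters onto two ecotypes maps clusters 1 and 3 to the same ecotype
  and produces *exactly zero* label correlation by symmetry, which would
  make the coupling parameter unobservable in the statistic the pipeline
  reports;
* the flip branch draws from *all* ecotypes, so `coupling = 0` yields
  independent labels (r ≈ 0) and `coupling = 1` identical ones — the two
  calibration points the tests pin.

**Phenotypes.** log-mass and log-length are linear in sex (M = 1), age,
northing, season dummies (fall reference) and individual homozygosity HL,
plus a management-unit intercept ~ N(0, σ_unit²) and residual noise.
Default coefficients for log-mass (sex 0.55, age 0.05/yr, northing 0.10,
spring 0.05, summer 0.07, HL 0.65, intercept 3.92; σ_unit = 0.15,
σ_resid = 0.20) put simulated masses in a realistic 60–400 kg range with
a positive homozygosity–fitness association of the magnitude the
hierarchical models should detect.  Ages are truncated-geometric on
2–25 years (capture programmes rarely collar cubs; old bears are rare),
coordinates are planar with one northing unit per management-unit box, and
no geodesy is used anywhere.

**Translocations.** Each event carries a year (uniform 1974–2012), a
source and a destination unit.  With probability `p_cross` the event
crosses units; cross-unit events are northward with probability
`p_north`.  The direction is drawn *first* and the unit pair second,
uniformly among compatible pairs — drawing the source first would bias
the realised northward share below `p_north` whenever the source sits at
the range edge.  Defaults reproduce the recorded scenario: 362 events,
229/362 cross-unit, 204/229 northward.

**Seeding.** One global integer seed is expanded through
`numpy.random.SeedSequence` spawn keys into independent per-stage
substreams, so identical (config, seed) pairs give byte-identical output
files and stages can be regenerated independently.

**What the generator does not emulate.** No GPS fix-level spatial or
temporal autocorrelation (use proportions are drawn directly; the fix
expander is a thin multinomial convenience, 1000 fixes/individual by
default), no landscape rasters, no pedigree structure beyond the
parent–offspring constructions built inside individual tests, no
linkage or null alleles, and no missing data unless `missing_rate` is
set.  Tests passing on these simulations demonstrate the *estimators'*
correctness and calibration, not robustness to autocorrelated telemetry
or genotyping artefacts.

## Genetic statistics

Homozygosity by loci weights each locus by its information content:

    HL_i = Σ_{l ∈ hom(i)} E_l / (Σ_{l ∈ hom(i)} E_l + Σ_{l ∈ het(i)} E_l),

with E_l = 1 − Σ_a p_a² from the full sample and missing loci excluded
from both sums.  Sample (not small-sample-corrected) expected
heterozygosities are the default weights; an `unbiased_he` flag switches
to the 2n/(2n−1) variant.

Queller–Goodnight relatedness uses the textbook per-locus numerator
0.5(δ_ac+δ_ad+δ_bc+δ_bd) − p_a − p_b and denominator 1 + δ_ab − p_a −
p_b, ratio-of-sums over loci, symmetrised as the mean of the two ordered
estimates.  Frequencies come from the full sample including the focal
pair: at n ≈ 88 the induced bias is far below the estimator's sampling
noise, and the simplification keeps the estimator a pure function of the
table.  Values can exceed [−1, 1] slightly when rare alleles shrink the
denominator; raw values are kept (no clamping) so that downstream Mantel
tests see the actual estimates.

The coancestry matrix is plain allele sharing, f_xy = mean over shared
typed loci of (δ_ac+δ_ad+δ_bc+δ_bd)/4 — the probability that one allele
drawn from each individual is identical in state.  A pedigree-
reconstruction coancestry (virtual-ancestor simulated annealing) would
estimate identity by descent instead; the Mantel machinery downstream
needs only *some* genetic similarity matrix, and the allele-sharing form
is deterministic and exactly testable.

The Hardy–Weinberg test is a Monte-Carlo exact test: gene copies at a
locus are pooled and randomly re-paired B times (default 10 000), and the
two-sided p-value compares the observed heterozygote count against the
permutation null with the add-one correction (p ≥ 1/(B+1) always).

Genotype PCA builds the individuals × allele-indicator matrix (per-allele
counts 0/1/2, column-mean imputation for the few missing genotypes),
column-centres it and eigendecomposes the covariance matrix.  Axis signs
follow one fixed convention — the largest-|loading| element of each axis
is made positive — so runs are comparable.

## Clustering

**Ecotypes.** Squaring the absolute difference of transformed use
proportions is exactly squared Euclidean distance, so the K-means
objective (within-group SSE around centroids) is the exact group-distance
criterion.  The optimiser is simulated annealing: propose moving one
random individual to a random other group, accept improvements always and
deteriorations with probability exp(−ΔSSE/T), geometric cooling from
T₀ = 1% of the initial SSE down to 10⁻⁶·T₀ (the schedule endpoints are a
design choice; step/restart counts are caller-visible).  ΔSSE is
evaluated in O(d) from group sums and counts.  Desk-scale defaults
(20 000 steps, 5 restarts) reach the exhaustively verified global optimum
on all tested small instances; full-scale settings (5·10⁶ steps, 100
restarts, k to 20) remain expressible.

Cluster number: the Calinski–Harabasz pseudo-F (SSB/(k−1))/(SSW/(n−k)) is
the workhorse.  The spherical-Gaussian BIC, n·d·ln(SSE/(n·d)) +
k·d·ln(n), is provided for comparison but a caveat is documented: its
k→k+1 change depends only on the SSE *ratio*, which for blob-like data
always beats the k·d·ln(n) penalty, so argmin-BIC typically saturates at
the top of the scanned range rather than resolving a cluster number.
The test suite asserts exactly this contrast (pseudo-F finds the planted
k; BIC saturates).

**Genetic clusters.** The admixture model: each allele copy of individual
i originates from cluster c with probability ∝ q_i[c]·p_c(locus, allele);
q_i ~ Dirichlet(α = 1), cluster frequencies ~ Dirichlet(1), both updated
by conjugate Gibbs steps with the latent origins sampled exactly.  The
correlated-allele-frequency prior of full structure-style software is
deliberately replaced by independent Dirichlet frequencies: conjugate,
fast, and only less sensitive at very low divergence.  Q is the posterior
mean of q over retained sweeps (20% burn-in, thinning 10), hard
assignment is argmax Q, and the per-sweep data log-likelihood trace feeds
the Evanno criterion ΔK(k) = |L̄(k+1) − 2L̄(k) + L̄(k−1)| / sd_rep(L(k)),
endpoints undefined.  Label switching within a chain is possible in
principle; at the divergence levels tested the chains stay in one
labelling, and replicate log-likelihoods (not labels) are what ΔK
consumes.

**Assignment correlation.** The ecotype/genotype association statistic is
the plain Pearson correlation of the two integer label vectors — kept
deliberately, because that is the field's reported statistic — together
with a sensitivity report: the maximum |r| over all relabelings of both
label sets.  The report matters: relabeling a binary vector is affine and
cannot change |r|, but relabeling a k ≥ 3 vector can move r from ≈ 0 to
its ceiling, and inferred cluster labels are arbitrary.  The raw r is
only interpretable jointly with this bound.

## Mantel machinery

r is the Pearson correlation of strictly-lower-triangle vectors
(diagonals never enter).  The permutation null permutes rows and columns
of one matrix simultaneously; p carries the add-one correction and is
one-sided *in the direction of the observed r* by default, matching how
signed one-sided correlations are conventionally reported.  Two
consequences are documented rather than hidden:

* the sign-adaptive one-sided test rejects ~10% of nulls at nominal 5%
  (it is min(p_lower, p_upper) without doubling); calibration studies in
  the tests therefore use a fixed direction (`alternative="greater"`),
  and a two-sided mode exists;
* matrices are used exactly as supplied — relatedness is a similarity,
  distances are distances — so a *negative* G~E correlation means related
  pairs are ecologically similar.

Partial Mantel residualises both triangle vectors by OLS (with
intercept) on one or two control triangles and correlates the residuals;
the null follows Legendre's residual-permutation method (the residuals of
the first matrix are reconstituted into a symmetric matrix whose
rows/columns are permuted jointly), which controls type-I error better
than raw-matrix permutation when controls are autocorrelated.  Collinear
controls (condition number > 10⁸) and controls that explain a matrix
completely are errors, not silent degeneracies.

Confidence intervals: the 95% CI is a percentile bootstrap over
*individuals* (resampled submatrix correlation, self-pairs dropped,
controls re-residualised inside each replicate).  Permutation quantiles
describe the null distribution, not the estimator's sampling
distribution, so they are not the default — but a permutation-quantile
mode is provided for compatibility with permutation-software
conventions.

The `ibe_suite` battery runs, per genetic metric (relatedness and
coancestry): S~E and E~D for each ecological axis, G~E per axis, G~D,
G~S, and the two partial models G~D|E*+S and G~E*|D+S, where E* is the
axis with the strongest simple |G~E| for that metric (3a + 4 rows for a
axes).

## Hierarchical heterozygosity–fitness models

Responses are log mass, log straight-line length (logs ensure positive
support; back-transformed predictions are positive by construction) and
the body condition index — the standardised residual of ln(mass) on
ln(SLL), mean 0 and sd 1 by construction.

Design construction is complete-case (rows with any missing covariate are
dropped and counted), fall is the season reference, a k-level cluster
covariate becomes k−1 dummies against the last (highest-label) cluster,
and continuous covariates are standardised by default — good sampler
conditioning, and coefficients on a comparable scale.  Recovery studies
that compare against generating coefficients switch standardisation off.

The model suite mirrors a four-model design per response: M1 base (sex,
age, northing, season), M2 = M1 + HL, M3 = M2 + hard cluster assignments,
M4 = M2 + PC scores, with an HL×sex interaction ('x') and unit-varying HL
slopes ('y') fitted as extensions of the DIC-best HL model.

Sampling is blocked Gibbs with fully conjugate updates (fixed effects
jointly via Cholesky; unit intercepts, hypermean, hypervariance, optional
unit slopes, residual variance).  Priors are conventional vague choices:
N(0, 100²) on fixed effects and hypermeans, inverse-gamma(0.001, 0.001)
on variances.  Defaults: 2 chains (any diagnostic needs ≥ 2), 3000
iterations, 1000 burn-in.  Convergence is summarised by Gelman–Rubin
R̂ = √(((n−1)/n·W + B/n)/W) per parameter with the < 1.1 convention;
non-convergence is a flag, not an error.

DIC uses the *conditional* Gaussian likelihood given the unit effects
(the common JAGS convention): D(θ) = −2 log N(y | Xβ + α_u (+ γ_u·HL),
σ²), Dbar the posterior mean deviance, pD = Dbar − D(posterior means),
DIC = Dbar + pD.  With this convention pD approximates the effective
number of parameters including the partially pooled unit effects.  DIC is
invariant to thinning up to Monte-Carlo noise (tested).

The single-locus ("local effect") F-test asks whether an HL association
is driven by one locus: on top of the base covariates, a restricted OLS
model adds one combined homozygosity predictor — the *unweighted mean* of
the per-locus 0/1 indicators, chosen so the restricted model is exactly
nested in the full model with all L indicators (HL's He-weighted form is
not in the indicators' column span).  F = ((RSS_r − RSS_f)/(L−1)) /
(RSS_f/(n − p_f)), df₁ = L − 1 (14 for a 15-locus panel); collinear
indicator columns are dropped with the df adjusted.

## Validation scale and known limitations

The acceptance-style checks run at deliberately chosen problem sizes that
keep the whole suite in minutes on one CPU while leaving no statistical
ambiguity: 1000 Mantel null simulations × 999 permutations at n = 50;
exhaustive K-means verification at n ≤ 10, k ≤ 3; admixture recovery at
n = 100, FST = 0.25, 20 000 sweeps; 200 hierarchical-model recovery
replicates at n = 500 with 2 × 2000-iteration chains; 20 DIC selection
replicates at n = 200.  Full-scale settings (10 000 permutations, 10⁶
sweeps, k to 20, 100 restarts) remain reachable through configuration.

Known limitations: the admixture sampler has no correlated-frequency
prior, so very weak divergence (FST ≲ 0.02) is harder to resolve than in
F-model software; Mantel-type tests inherit the method's known
sensitivity to autocorrelation structure not captured by the controls;
the Pearson label correlation is a label-ordering-dependent statistic and
must be read with its sensitivity bound; BCI assumes a common allometric
slope across sexes and ages; and the pipeline treats GPS fixes as
pre-classified points, taking no account of location error or habitat
misclassification.
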