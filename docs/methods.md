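# Methods

## Data model and preprocessing

Inputs are (a) a line×marker SNP table — diploid calls AA/AB/BB or dosages
0/1/2 with missing values, coded as the count of the B (alternate) allele —
and (b) a long-format table of per-(line, site, trait) adjusted means,
optionally with standard errors from the first-stage trial analysis (which
is out of scope here; the package consumes adjusted means).

Marker QC keeps markers with call rate strictly above 0.80 and minor allele
frequency strictly above 0.05 ("above"/"greater than" are strict by
convention). MAF is computed on non-missing calls only, *before*
imputation, because mean imputation would bias allele frequencies toward
the observed mean. Missing calls are then replaced by the marker's
non-missing mean dosage, and each marker is centered and scaled by its
sample (n−1) standard deviation. Prediction-set genotypes are standardized
with the training-set means/SDs so GEBVs are comparable across sets.
Constant (zero-SD) markers are an error at standardization: they should
have been removed by the MAF filter.

## Genomic relationships, structure, heritability

The GRM is VanRaden's method 1, `G = ZZ'/(2Σ p_k(1−p_k))` with
`Z = M − 2P` and allele frequencies estimated from the sample, optionally
on a seeded random marker subset (recorded in the result for
reproducibility). Rows of G sum to zero by construction; a fully inbred
line has expected diagonal 1+F ≈ 2.

Structure is assessed by PCA on G. Each leading eigenvalue is tested
against the Tracy–Widom (β=1) null after removing previously tested axes.
The effective marker count is re-estimated from the remaining spectrum by
the moment identity E[s₂/s₁²] = 1/n + 1/m for a white Wishart spectrum
(s₁, s₂ the first two spectral moments, m the number of eigenvalues); this
estimator is calibrated on the VanRaden spectrum — on unstructured
genotypes the test rejects at ~1% for α = 0.01, and two subpopulations at
Fst ≈ 0.1 are detected essentially always (both properties are exercised in
the test suite). Tail probabilities interpolate a fixed table of TW₁
quantiles (0.50–0.999); beyond the table an exponential tail is used, so
extreme p-values are approximate.

Genomic heritability is REML under y = 1μ + g + e, g ~ N(0, Gσ²_g): after
one eigendecomposition of G the restricted likelihood is a 1-D function of
h² = σ²_g/(σ²_g+σ²_e), maximized by bounded Brent search plus a
golden-section polish (Brent's bounded method stops at ~√ε·|x|, too coarse
for the scale-invariance contract). The trait is standardized internally so
h² is exactly location/scale invariant up to the ~1e-7 flat region that
floating-point evaluation of the likelihood imposes. The SE is the inverse
curvature of the profile at the optimum (observed information); negative
eigenvalues of G are floored at 1e-8.

## Whole-genome regression samplers

All five priors share the Gibbs skeleton: intercept (flat prior), a sweep
of coefficient full conditionals, variance components, and the residual
variance, with per-record precision τ_i = w_i/σ²_ε supporting both
inverse-squared-SE weighting of adjusted means and heterogeneous site
variances. Marker sweeps are numba kernels updating a running residual, so
one coefficient update is O(n); retained chains store variances, π and the
conditional Gaussian deviance.

Hyperparameters (unobservable from data descriptions alone, so fixed by the
conventions of the standard Bayesian genomic-regression software): the
scaled-inv-χ² scale sums are set so the prior mode allocates r2_prior = 0.5
of the phenotypic variance to the markers (divided by π₀ for the
spike-and-slab slabs) and the rest to the residual, with df₀ = 5; π has a
Beta prior with mean π₀ = 0.5 and weight 10. For BayesA the scale is itself
unknown, with a Gamma(1.1, rate matched to the r2-derived value) prior
updated by its Gibbs conditional — without this, BayesA's per-marker
variances absorb noise at p ≫ n and overstate the genetic share of variance
(h² ≈ 0.8 for a truth of 0.5 in our benchmarks). BayesB/C adapt their
sparsity through π instead, so their slab scale stays fixed; letting both
the slab scale and π adapt degraded π identifiability noticeably.
Spike-and-slab updates integrate the slab coefficient out analytically
for the inclusion odds, then draw the coefficient conditionally. Sampled
variances are floored at 1e-10. A non-finite chain state raises an error
naming the iteration.

RKHS regression samples the kernel effect in the eigenbasis of K (linear
`K = G` or Gaussian `K = exp(−h·D²/median(D²))` on standardized genotype
rows; h = 1 by default). Eigencomponents reuse the Gaussian sweep with
per-component prior variance λᵢσ²_u, so heteroscedastic residuals come for
free; predictions for new lines use α̂ = K⁻¹û.

DIC uses the conditional Gaussian deviance given the sampled state:
D̄ = mean of the retained deviance chain, p_D = D̄ − D(θ̂) at the posterior
means, DIC = D̄ + p_D. The model-implied h² reported by a fit is the
posterior mean of var(current genomic values)/var(y) computed per retained
draw from the running residual; the variance of the posterior-mean GEBV is
systematically shrunken (≈0.31 for a truth of 0.5 in our benchmarks) and is
not used.

Default chain lengths are 210,000 iterations, 10,000 burn-in, thinning 20
(the full-fidelity profile); tests and the `--fast` CLI profile use
6,000/1,000/5, which the recovery studies below show is adequate for
posterior means at the benchmark sizes.

## Multi-environment models

Stacked records over J sites are fitted by three nested model classes with
per-site intercepts and per-site scaled-inv-χ² residual updates throughout:
independent single-site fits (delegating to the single-site sampler),
across-site (one shared effect vector), and M×E (main effects updated
against all records pooled, per-site deviations against that site's
records). Under BayesB each component — main and each site deviation —
carries its own independently Beta-updated π, reported separately. The
prior variance share r2 = 0.5 is split evenly between main and deviation
components in the M×E model. Records are whatever cells exist: the sampler
conditions on observed (line, site) cells only, which is what CV2 masking
requires. A site sharing no lines with any other site makes the interaction
unidentifiable and is rejected. `gebv_site` excludes the site intercepts
μ_j (correlation-based accuracy is location invariant); add μ_j for
trait-scale predictions.

## Evaluation protocol

Partitions: `single_site_random` and `cv1` assign whole lines to
TRN/TST (70/30 by default, 50 replicates in the full protocol); `cv2`
masks ~30% of (line, site) cells such that every line keeps at least one
training site, redrawing until per-site masking is within ±5 percentage
points of the target. All partitioning is seeded and reproducible.

Per replicate and site, on the test cells: Pearson correlation between
predictions and observed adjusted means; scaled accuracy = correlation /
√h² (h² supplied per site — full-data GRM-REML estimates on real data, the
generator's realized h² in simulation studies; values above 1 are reported
as computed, with a warning); bias = OLS slope of predictions on observed
values (≥1 no bias, <1 overestimation). Aggregates are mean ± SE (SD/√reps)
over replicates, recomputable from the stored per-rep rows.

Selection efficiency is the coincidence index between two models' top
fractions: n_sel = round(0.20·n) lines selected, chance = round(0.20·n_sel)
expected by chance, efficiency = (c − chance)/(n_sel − chance)·100 floored
at 0 (both roundings to nearest integer, so 116 lines give 23 and 5, and
c = 10 gives 28%). Under independent rankings its expectation is ~0.

## Synthetic data generator

The generator emulates the structure the analysis assumes: founder allele
frequencies uniform on the MAF range (0.05–0.5), family frequency vectors
drifted Balding–Nichols style (Fst 0.15, 12 families by default), lines
drawn near-inbred (dosage 0/2 with 3% residual heterozygosity), ~4.8%
missing calls. Effects are spike-and-slab: markers nonnull with probability
π = 0.3; nonnull markers get a main effect ~N(0, σ²_b0 = 1) and per-site
deviations ~N(0, σ²_bj = 0.5), i.e. a 2:1 main-to-interaction variance
ratio giving moderately positive between-site correlations. Phenotypes are
y = site mean + TBV + e with TBV = X(b₀ + b_j) on the standardized genotype
scale; the drawn noise is centered, orthogonalized against the TBVs and
rescaled so each site's realized h² equals its target (0.6/0.5/0.4/0.3 by
default) exactly — residual variances are solved from realized var(TBV),
never by rescaling the TBVs, so effect sizes keep their scale.

For the single-site recovery benchmark (n = 300, p = 1000, h² = 0.5,
π = 0.3) the population uses 30 families (~10 lines each): with very few
families the apparent heritability of a dataset is weakly identifiable at
this n (GRM-REML SEs ≈ 0.13), which no estimator can overcome; family size
~10 keeps the population realistically related while recovery to ±0.12 is
meaningful. Under those conditions BayesB recovers h² within ±0.12, covers
the true π with its 95% credible interval, and reaches cor(GEBV, TBV) ≥ 0.7
in ≥90% of seeded replicates (computed in the test suite).

What the generator does *not* emulate: linkage disequilibrium and shared
long haplotypes. Markers are generated in linkage equilibrium, so (a) the
leading PCs of the GRM explain far less variance than in real breeding
populations even with genuine family structure, (b) the Tracy–Widom test
flags the simulated discrete families as structure, whereas a smoothly
admixed real population may test negative despite large PC shares, and
(c) GRM-REML heritability on 100–215 simulated lines carries much larger
SEs than the same analysis on real data whose relatedness is block-like.
Passing tests therefore validate the estimators and their contracts, not
LD-dependent behavior such as marker-density response.

## Problem sizes and numerical choices

Tests and analysis drivers run at reduced sizes chosen to keep the full
suite in the minutes range while leaving all statistical contracts
testable: recovery studies at n = 300, p = 1000 with the 6,000/1,000/5
chain profile; multi-environment structural checks at n ≈ 120, p = 300–400
over ~10 replicates; evaluation protocols at 5–10 partitions instead of 50.
The full-fidelity settings (215+ lines, 210,000-iteration chains, 50
partitions) are the library defaults and drop in unchanged.

Known limitations: single chain by default (split-chain diagnostics are
logged, not enforced); DIC uses the conditional (not marginal) deviance;
Tracy–Widom p-values are table-interpolated; the deviance-based model
comparison and π reports assume Gaussian residuals on the adjusted-mean
scale; no LD simulation (above); no multi-trait or
environmental-covariate reaction-norm models.
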