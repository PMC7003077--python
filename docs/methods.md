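# Methods

## The analysis this package implements

The target design is two-stage genomic selection on half-sib families of an
outcrossing forage.  Maternal parents from several closed breeding
populations are polycrossed; seed harvested per mother defines a half-sib
family; families are evaluated in balanced multi-location row-column trials;
the mothers are genotyped by low-coverage GBS.  Stage one estimates variance
components and family adjusted means (BLUPs) from the trial; stage two
regresses those adjusted means on genome-wide marker information to predict
breeding values for families, including unphenotyped ones.

## Trial mixed models and REML

Three standard models are provided.  The across-location model is

y_ijklmn = μ + g_i + s_m + (gs)_im + p_n + b_nml + r_nmlj + c_nmlk + ε,

with family g, family-by-location (gs), replicate b (nested in
location × population), row r and column c (nested in replicate) random, and
location s plus population p fixed.  The single-location model drops s and
(gs); the within-population model drops p.  Any random term may carry a
supplied covariance among its levels; in practice that is the family term
with a genomic relationship matrix G, i.e. g ~ N(0, σ²_g G).  The
family-by-location covariance stays identity: the data carry no information
to structure a G×E covariance with only two environments.

Estimation is average-information (AI) REML on the full covariance matrix
V = Σ σ²_i Z_i K_i Z_iᵀ + σ²_ε I:

* gradient and AI matrix computed through the thin Z factors (no per-term
  n × n products), one Cholesky of V per iteration;
* AI step with step-halving whenever the proposal leaves the parameter space
  or decreases the restricted likelihood; EM update as fallback (monotone,
  slow, but safe);
* an active set pins a component at the zero boundary whenever it sits at
  the boundary with a negative gradient, and releases it if the gradient
  turns positive — without this, true-zero components make the AI step fail
  indefinitely and the optimizer crawls;
* negative proposals are truncated at 1e-10 × the phenotypic variance,
  i.e. effectively zero; reported estimates at the bound are rounded to 0;
* convergence: largest relative component change < 1e-8 (free components
  only) and stable log-likelihood; maximum 200 iterations, with the
  iteration trace attached to any convergence error.

Standard errors come from the inverse AI matrix at the optimum.  BLUPs are
u_i = σ²_i K_i Z_iᵀ P y.  On balanced data the REML estimates coincide with
expected-mean-squares ANOVA estimators, which the tests exploit as an
independent oracle (agreement to 1e-8).

Significance of a variance component uses the likelihood-ratio test against
the model without the term, with the ½χ²₀ + ½χ²₁ boundary mixture
(p = ½ P(χ²₁ ≥ LR), p = 0.5 at LR = 0).  A Wald z from the AI standard error
is reported alongside for comparison with ±SE tables.  Simulation places the
empirical type-I error at ≈ 0.05 (the acceptance suite re-measures it over
500 null fits).

Family-mean heritability is h² = σ²_g / (σ²_g + σ²_gs/s + σ²_ε/(s·b)) with
s locations and b replicates — repeatability when σ²_g is the
across-population family variance under identity covariance, narrow-sense
when estimated within a population, genomic (h²_g) when the family
covariance is a marker-based G.  Note an identity G reproduces the
repeatability exactly, and more generally a family-level G cannot separate
marker-linked from unlinked family variance unless its structure departs
strongly from identity, so h²_g is expected to track repeatability closely
(as multi-population half-sib panels indeed show).

Genotypic correlation between traits uses the sum-trait identity
Cov_g(x,y) = [σ²_g(x+y) − σ²_g(x) − σ²_g(y)] / 2 with three fits of the same
model, then r_g = Cov_g / √(σ²_g(x) σ²_g(y)).  This equals the MANOVA
cross-product estimator on balanced data (tested, not assumed) and remains
defined under mild imbalance.  Phenotypic correlation is the Pearson
correlation of family BLUPs.

## Kinship from low-coverage GBS

Naive genotype calls at depth d miss heterozygotes with probability 2^(1−d)
(both reads must come from the same chromosome).  Two consequences matter:
site statistics show an apparent heterozygote deficit (hence the
Hardy–Weinberg filter only removes strongly *negative* D̂, i.e. artifactual
heterozygote excess from collapsed paralogs), and the VanRaden self-
relatedness is inflated because a miscalled heterozygote contributes
(0 − 2p)² or (2 − 2p)² instead of (1 − 2p)².

The depth-adjusted (KGD) estimator works on the reads themselves.
Off-diagonals are centered cross-products over the SNPs covered in *both*
individuals, scaled by 2 Σ p(1−p) over the same subset — no imputation, and
unbiased because E[naive call | true dosage] equals the true dosage.  For
the diagonal, the excess of the naive self cross-product at a true
heterozygote of depth d is exactly 2^(1−d) (independent of allele
frequency), and the observed het indicator g(2−g) fires with probability
1 − 2^(1−d), so subtracting g(2−g)/(2^(d−1) − 1) per SNP removes the
inflation in expectation.  Depth-1 SNPs are excluded from the diagonal sum
(one read can never reveal a heterozygote, so the bias there is not
estimable from the observed call); the denominator runs over the same
depth-≥2 subset.  The estimator is validated against simulation truth
(diagonal unbiased for 1 + F at mean depth 2 while the naive diagonal is
inflated by ~0.6) and against pedigree expectations (half-sib pairs at 0.25
regardless of depth).  Allele frequencies for both matrices are estimated
from naive calls over covered individuals.  Pairs with zero shared SNPs are
flagged missing, and are zero-filled with a logged warning only when a
complete matrix is required for model fitting.

## Prediction

GBLUP solves y = 1μ + u + ε with u ~ N(0, σ²_u G) on the training families
(variance ratio re-estimated by REML inside every training set, unless fixed)
and propagates GEBVs to any identifier through its rows of G; with a VanRaden
G this is identical to ridge regression on centered dosages at
λ = σ²_ε / (σ²_u / 2Σp(1−p)) (tested to 1e-8).  KGD-GBLUP is the same solve
with the depth-adjusted matrix.

BayesCπ is a Gibbs sampler over per-marker inclusion indicators (a marker is
excluded with probability π), a shared effect variance, the intercept, the
residual variance and π itself.  Priors: scaled-inverse-χ² with 4 degrees of
freedom on both variances, scales set so markers and residual each start
with half the phenotypic variance; uniform (Beta(1,1)) prior on π.  Defaults
are 10,000 iterations with 2,000 burn-in; tests and examples run shorter
chains (stated sizes below) since the posterior mean of the marker score
stabilizes quickly on these panel sizes.  With π fixed at 0 and fixed
variances the sampler's posterior mean reproduces the ridge/GBLUP solution,
which the tests use as an exactness check.

The bias diagnostic regresses observed adjusted means on GEBVs; a slope of 1
means calibrated predictions (E[obs | GEBV] = GEBV).  The reverse regression
is also available but its expectation is the squared accuracy, not 1.

## Cross-validation

Predictive ability is the Pearson correlation between held-out adjusted
means and GEBVs.  k-fold CV (default 10-fold) pools the held-out predictions
within one randomization, giving one correlation per randomization (default
5), and reports their mean.  Monte-Carlo CV draws independent 80/20 splits
(default 500).  Within-population CV draws half of *every* population for a
joint training set (equal representation) and scores each focal population's
held-out half.  The marker ladder subsamples markers uniformly without
replacement — rung size = floor(fraction × total), so 1 % of 1,093,464
markers is 10,934 — rebuilds a VanRaden matrix per rung with re-estimated
allele frequencies, and runs Monte-Carlo CV per rung.  All schemes log their
partitions and are bit-reproducible under a fixed seed.

## The synthetic-data generator

The generator mirrors the study conditions and is the substrate for every
simulation-based test:

* **Populations.** Five populations of 102–117 maternal parents (default
  counts (102, 104, 117, 110, 84), 517 total).  Ancestral allele frequencies
  are uniform on the configured MAF range (folded at 0.5), perturbed per
  population by a Balding–Nichols draw at F_st = 0.05.
* **Relatedness.** Parents within a population are crosses among a finite
  ancestral pool (default 20), reflecting closed advanced breeding
  populations.  This matters: with unrelated founders the GRM is ≈ I + noise
  and genomic prediction has almost nothing to work with — in this design
  predictive ability is carried mainly by relatedness capture, not by
  marker–QTL linkage.
* **Genetics.** A configurable number of causal markers (default 300 of
  3,000) with normal or point-mass-mixture effects; maternal breeding values
  are rescaled to variance 2σ²_g per trait, optionally correlated across
  traits through a supplied correlation matrix.
* **Family effects.** A family inherits half its mother's breeding value;
  the other half of σ²_g is an independent pollen-pool/Mendelian draw.
  Markers on the mothers can therefore explain at most half of the family
  variance — informative but imperfect, as in a real polycross.
* **GBS reads.** Depth is zero-inflated: missing with the configured
  probability (default 0.23), otherwise zero-truncated Poisson with the
  configured mean of the covered cells (default 2.98).  A plain Poisson
  cannot reproduce a mean near 3 together with ~23 % missingness, which is
  why the two parameters are separate.  Alternate reads are
  Binomial(depth, dosage/2), giving the 2^(1−d) het-undercall by
  construction.
* **Trial.** Balanced: every family appears once per replicate per location,
  assigned to a near-square row-column grid per (location, population,
  replicate) block.  Plot value = mean + location + population fixed offsets
  (drawn once at half the phenotypic SD) + family + family-by-location +
  replicate + row + column + residual, each at its configured variance.
  Default trait variances are the sodium-like row (σ²_g = 2.32e-3,
  σ²_gs = 0.25e-3, σ²_ε = 3.93e-3; family-mean repeatability 0.75 at
  2 × 3).  Replicate/row/column variances default to 0 and are set to small
  positive values (2e-4) where a test needs them.
* **Determinism.** One seed feeds separate child streams per stage
  (frequencies, genotypes, effects, reads, trial), so re-running one stage
  does not consume another's randomness.  Everything is byte-reproducible
  under a fixed seed.

What the generator does *not* emulate: linkage and LD decay (markers are
unlinked, so marker–QTL LD beyond relatedness is absent), multi-generation
selection, repeated check plots, spatial autocorrelation beyond row/column
effects, and genotyping error other than binomial read sampling.  Passing
tests therefore demonstrate correctness of the estimators under the assumed
sampling models, not robustness to, e.g., spatially correlated residuals or
sequencing artifacts.

## Problem sizes and numerical choices in the test suite

Simulated panels are scaled below the real study so the whole suite runs
comfortably on one CPU: typically 100–300 families, 400–5,000 SNPs, with
40,000 SNPs only for the marker-density ladder (its 5 % rung must retain a
low-noise GRM, since rung behavior is governed by the absolute marker count
through GRM sampling noise ~ 1/√m, not by the fraction).  Component-recovery
coverage uses 100 replicates of a 150-family trial; the type-I-error check
uses 500 null fits of an 80-family design; BayesCπ comparisons run 1,200
iteration chains.  These sizes are the package's test-design choice; all
estimators accept study-scale inputs.

Numerical details worth knowing: the zero-truncated Poisson is sampled by
rejection; GRM construction uses int16 read counts to keep dense panels
cheap; `reml_fit` materializes V (dense) and is intended for up to a few
thousand plots; a supplied family covariance is "bent" (eigenvalues clipped
at 1e-8) before fitting because estimated kinship matrices — the KGD
estimator in particular — need not be positive semi-definite; correlations
with zero-variance inputs return flagged NaN rather than raising inside CV
loops; r_g is clamped to ±1 with a warning when component noise pushes it
marginally outside.

## Known limitations

* No spatial (AR1) row/column models, no multi-trait mixed models, no
  single-stage genomic selection, no de-regression of BLUPs.
* The REML engine is dense; panels far beyond ~5,000 plots would need a
  sparse or eigendecomposition-based path.
* BayesCπ samples markers in a Python loop; chains over ~10⁵ markers are
  slow (the intended stage-two inputs are family-level adjusted means with
  up to a few thousand markers).
* The KGD diagonal correction assumes binomial read sampling without
  sequencing error or allelic bias.
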