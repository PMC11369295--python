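# Methods

This note documents the models, numerical choices and limitations of
`adipocop`. Everything stated here is computed by the package's tests or the
acceptance script; nothing is quoted from external results.

## Joint copula model of the two fat phenotypes

The analysis outcome pair is (log SAT, SAT/TAT): SAT mass is natural-log
transformed to make it approximately Gaussian, the ratio is analyzed on its
raw scale. Per gene, both outcomes are regressed on an intercept, the five
covariates (sex, age, smoking, physical activity, education; categoricals
dummy-coded against their first level) and the gene's Yeo-Johnson-transformed
expression. The joint distribution couples the two Gaussian marginal models
through the BB1 Archimedean copula

    C(u1, u2) = { [ (u1^-phi - 1)^theta + (u2^-phi - 1)^theta ]^(1/theta) + 1 }^(-1/phi),
    phi > 0, theta >= 1,

whose implied Kendall's tau is `1 - 2/(theta*(phi+2))`. The density and
h-function are evaluated analytically on the log scale (`expm1`/`logaddexp`
throughout) so that likelihoods stay finite deep into the corners of the
unit square.

**Estimation.** One-stage maximum likelihood over all free parameters
(both coefficient vectors, both residual scales, both copula parameters) on
the unconstrained scale (log sigma, log phi, log(theta-1)). Two-stage
estimation (margins first) was rejected because the Wald standard errors
should come from the full observed information. Numerically the design
columns and the outcomes are centered/scaled internally and the estimates,
covariance and log-likelihood mapped back exactly — without this,
genes whose transformed expression lives on very different scales stall the
quasi-Newton optimizer. Optimization is L-BFGS-B started from the marginal
OLS fits and a tau-inversion copula start (theta = 1 + 1e-3,
phi = 2*tau/(1-tau) from the residuals' sample tau), followed by damped
Newton refinement with the centered-difference gradient and observed Hessian
until the score's max-norm is below ~1e-4 (finite-difference noise floor).
The reported covariance is the inverse observed information at the final
point; Wald tests use the N(0,1) reference, two-sided. A non-converged fit
restarts from deterministically perturbed starts; if it still fails the gene
is reported with NaN p-values but stays in the Bonferroni denominator.

**Calibration.** Under the null at n = 160 the Wald test's empirical type-I
error at nominal 0.05 is ~0.06 (2,000 replicates; inside the exact binomial
99% band, but at its upper edge): the large-sample reference is mildly
anti-conservative at this sample size. Asymptotically (n = 2,000) the test
matches the OLS t-test in the independence limit to a few percent. With
tau = 0.36 dependence and a shared effect on both outcomes the copula screen
is more powerful than per-outcome OLS (0.68 vs 0.60 at nominal 0.05 in the
acceptance simulation): the non-Gaussian copula coupling carries information
that single-equation least squares cannot use.

**theta = 1 boundary.** The BB1 domain boundary theta = 1 (Clayton) is the
generator's default dependence; the fitter parameterizes log(theta - 1) with
a lower bound, and fits at the boundary report theta ~= 1. The Wald test on
the expression coefficients is unaffected, but Wald intervals for theta
itself are not meaningful at the boundary.

## Expression preprocessing

TPM (rates count/length rescaled to 1e6 per sample) -> TMM -> low-expression
filter -> per-gene Yeo-Johnson, in that order. Two choices deserve note:

* **TMM on a normalized matrix.** Because the input to TMM here is already
  within-sample normalized (TPM), M-values are plain log2 ratios against the
  reference column with *no* library-size offset; a uniformly doubled column
  therefore receives a doubled factor (before the geometric-mean-1
  rescaling). Reference selection (upper quartile closest to the mean),
  double trimming (30% of M, 5% of A, each tail) and inverse-delta-method
  variance weights follow the standard TMM construction.
* **"Expressed" means value > 0.** The 25% filter keeps a gene expressed in
  exactly 25% of samples (the "less than" is strict) and is applied to the
  normalized matrix.

Yeo-Johnson lambda is found by bounded profile-likelihood search on
lambda in [-5, 5] (tolerance 1e-6); constant genes pass through unchanged
with lambda = 1 and a warning.

## Mendelian randomization

Instrument selection per gene and outcome: (i) membership in the gene's
cis-eQTL table rows; (ii) no covariate association at p < 0.001
(linear-regression Wald for age; Fisher's exact for the categorical
covariates — 2x2 tables exactly, larger tables by a seeded Monte-Carlo
conditional test with Patefield margin-preserving sampling and the
table-probability statistic); (iii) no outcome association at p < 0.001
conditional on expression and covariates; (iv) greedy Spearman pruning at
|rho| > 0.9, keeping the stronger eQTL of each pair (genomic-position
tie-break). Per-SNV exposure and outcome effects are covariate-adjusted;
missing genotypes are mean-imputed per SNV.

The IVW estimate is a GLS regression of outcome effects on exposure effects
through the origin, `theta = (bx' W bx)^-1 bx' W by`, `W = Omega^-1`. The
delta-weight covariance was frozen against a parametric bootstrap of the
summary-statistic covariance (simulating correlated SNVs at the individual
level and measuring Cov(by_hat - theta*bx_hat)):

    Omega_ij = rho_ij se_by_i se_by_j
             + theta0^2 rho_ij se_bx_i se_bx_j
             - theta0 psi rho_ij (se_bx_i se_by_j + se_by_i se_bx_j)

with theta0 the first-order estimate and psi the sample exposure–outcome
correlation — the multi-instrument generalization of the delta-method
variance of a ratio, which carries the correlation term with a negative
sign. It reduces exactly to first-order weights when se_bx = 0 and psi = 0.
Near-singular Omega receives a 1e-8 ridge (logged).

## Replication

Weights come from one multiple OLS of the (transformed) discovery expression
on all surviving instruments jointly (collinear SNVs reduced to a full-rank
subset, logged). The cohort-B score is the weighted allele-count sum over
the SNVs cohort B actually carries — discovery weights are never refit. The
association model uses log aSAT (log-transformed for consistency with the
discovery outcome) or aSAT/(aSAT+VAT), adjusting for age, sex, smoking and
education (physical activity is deliberately absent from the replication
model). Replication significance is nominal p < 0.05 per gene-outcome test
(configurable; no further correction by default).

## Enrichment

Classic term-by-term two-sided Fisher's exact tests (hypergeometric
enumeration with the conventional 1e-7 tie guard), after propagating gene
annotations up the term->ancestor closure (true-path rule). Terms with fewer
than `min_term_size = 5` annotated background genes are excluded from the
analyzed set and hence from the correction denominator (Bonferroni by
default; Holm and Benjamini-Hochberg available). Significant terms are
tallied by their highest-level parents — ancestors sitting directly below
the ontology root — with multi-parent terms counted once per parent and
orphans reported under `unmapped`.

## Synthetic cohorts: what they emulate, and what they do not

* **Genotypes.** Per-gene blocks of SNVs from a latent-Gaussian AR(1)
  haplotype model (`ld_decay` is the latent adjacent-SNV correlation;
  genotype correlation is the slightly attenuated thresholded-Bernoulli
  value, computable exactly by enumerating the nine genotype combinations),
  Hardy-Weinberg by summing two independent haplotypes.
* **Expression.** A unit-variance latent trait with a genetic component
  scaled to explain `eqtl_r2` (default 0.10) of variance, exponentiated onto
  a lognormal count scale (log-sd 0.3, so the genetic R^2 survives nearly
  unattenuated); the generative per-SNV slopes are emitted as a GTEx-layout
  eQTL fixture table.
* **Phenotypes.** Residual pairs sampled from the BB1 copula (phi from
  tau-inversion at the configured theta; default tau = 0.36 at theta = 1,
  giving phi = 1.125) and Gaussian-quantile transformed, so the marginal
  models stay linear-Gaussian with dependent errors. log SAT uses
  sex-specific location (log 20.1 / log 14.8) and sd 0.35, chosen to match
  a median-absolute-deviation-to-median ratio of ~0.26-0.29 for a lognormal;
  the ratio uses sex-specific levels 0.85 / 0.70 with sd 0.07 on the raw
  scale, clipped into (0.01, 0.99) with the clip count logged (warning above
  5%). TAT is derived as SAT/ratio so SAT < TAT holds by construction.
* **Covariates.** Sex-stratified: P(woman) = 88/160, age N(62.7, 8.4) for
  women and N(66.9, 8.3) for men, three-level smoking and education and
  four-level physical activity at the discovery cohort's frequencies. Age
  carries a small real effect on both outcomes (+0.003 / -0.001 per year)
  so covariate adjustment is non-trivial; the categorical covariates are
  phenotype-neutral by default.
* **Replication cohort.** Same SNV truth and expression weights, phenotypes
  aSAT (location log 9 / log 7) and VAT via an aSAT fraction (0.66 / 0.52),
  and an exome-capture availability mask keeping each SNV with probability
  0.5.

Not emulated: genome-wide LD structure beyond the AR(1) block, population
structure and relatedness, read-level sequencing noise, batch effects, and
pleiotropy (instruments act on outcomes only through expression). Passing
tests therefore validate the statistical machinery under the model's own
assumptions, not robustness to these real-data complications.

## Problem sizes and determinism

Desk-scale defaults keep every simulation fast while leaving sampling error
well below the assertion tolerances: null calibration uses 2,000 replicates
at n = 160; power comparison 200 effect genes; MR recovery 100 replicates at
n = 2,000 and MR null 500 replicates at n = 500; the tau-identity check uses
n = 50,000 per grid point; the end-to-end pipeline examples use 10-14 genes.
Every stochastic component takes an explicit seed (numpy `default_rng`), and
identical seeds reproduce cohorts, screen tables and pipeline manifests
bit-for-bit.

## Known limitations

* The Wald screen is slightly anti-conservative at n = 160 (~0.06 at nominal
  0.05); users wanting exact small-sample control should calibrate by
  simulation with the provided generator.
* Only the bivariate copula is implemented (the family is defined for
  general p).
* The Monte-Carlo Fisher test for r x c confounder tables has resolution
  1/(B+1) (default B = 4,999), coarse relative to the 0.001 filter
  threshold; raise `n_mc` for sharper decisions.
* Instrument selection and MR reuse the same individual-level sample, as in
  the one-sample design this mirrors; weak-instrument bias is mitigated by
  the stringent filters but not eliminated.
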