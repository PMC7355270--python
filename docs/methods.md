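# Methods

## Model

`twinade` fits the classical twin ADE covariance-structure model to raw
twin-pair data. For M phenotypes the expected 2M x 2M covariance of a pair is
built from component covariances `Sigma_A` (additive genetic), `Sigma_D`
(dominance) and `Sigma_E` (unshared environment, which absorbs measurement
error), each parameterized through a lower-triangular Cholesky factor
`Sigma_X = Delta_X Delta_X'`. The within-twin block is the sum of the three;
the cross-twin block weights A and D by the expected allele sharing of the
pair's zygosity — 1/1 for monozygotic, 0.5/0.25 for dizygotic twins. A
shared-environment component C is supported for completeness with cross-twin
weight 1 in both zygosities (the standard biometric specification); the
default model is ADE, the configuration the MZ/DZ correlation pattern of
this domain calls for (r_MZ > 2 r_DZ).

Teacher-rated phenotypes carry one additional latent rater factor per twin,
loading freely on every teacher-rated phenotype (a rank-1 addition
`lambda lambda'` to the within-twin block). The factors of the two twins
correlate 1 when the twins share a teacher and 0 otherwise, so the rater
covariance also enters the cross-twin block for same-teacher pairs. Whether
loadings are free per phenotype or constrained equal is an option; free is
the default because nothing forces two instruments to be equally sensitive
to a rater's style.

Sex enters the means only: per-twin mean = intercept + beta_sex * sex
(0 = boys, 1 = girls), with coefficients equal across twins and zygosities.
Opposite-sex DZ pairs share the same-sex DZ covariance structure; variance
components are not sex-moderated in the multivariate model (the univariate
sex-moderation LRT is provided to justify that choice on any dataset).

Assumptions inherited from the twin design: equal environments across
zygosities, random mating, no gene-environment interplay, multivariate
normality of the (transformed) phenotypes.

## Estimation

Each pair contributes the multivariate-normal log density of its observed
coordinates; missing coordinates are marginalized analytically by row/column
deletion (full-information ML, unbiased under MCAR/MAR). Pairs are grouped
by (zygosity, teacher sharing, missingness pattern) so each likelihood
evaluation performs one Cholesky factorization per group rather than per
pair, and the gradient is computed analytically via the standard
multivariate-normal matrix calculus (verified against central differences in
the test suite).

Optimization is multi-start L-BFGS-B (default 5 starts; the first uses
moment-based values, the rest jitter them with seeded noise, best final
likelihood kept — deterministic under a fixed seed). Starting values:
`Delta_E` from the Cholesky of half the pooled phenotypic covariance,
`Delta_A` from the Cholesky of 0.8 x the MZ cross-twin covariance
(eigenvalue-clipped to be PSD, floor 1e-6, since sample cross-moment
matrices need not be PSD), `Delta_D` = 0.05 I, mean parameters from
per-phenotype regressions on sex. The objective is the negative
log-likelihood per pair; the fit is flagged converged when the
central-difference gradient sup-norm on that scale is below 1e-5. Since
`Delta Delta'` is sign-invariant, signs are canonicalized post hoc:
nonnegative Cholesky diagonals (flipping whole columns) and a nonnegative
leading rater loading. Dominance-without-additive outcomes are legitimate —
estimates may sit at zero without being fixed there; no boundary constraints
exist beyond the Cholesky parameterization itself. A non-positive-definite
covariance during optimization yields a large penalty value, never an
exception; non-convergence after all starts is reported, never silent.

Standard errors: plain observed-information SEs (inverse numerical Hessian)
and the sandwich estimator `A^-1 B A^-1` with B the sum of per-pair score
outer products — the raw-data analogue of MLR-style robust errors. The MLR
scaling correction for likelihood-ratio statistics is *not* reproduced;
LRTs are plain, and this is a known approximation under non-normality.

The sex-moderation test fits a two-group (by sex) univariate model with
free vs equated A, D, E components (3 df; 1-df component-wise variants free
one component at a time). Opposite-sex pairs are excluded from both models
by default so the likelihoods stay nested; an option adds them to the
equated model only, which uses more data but makes the LRT approximate, and
is documented as such when used.

## Preprocessing

Subscale scores are item means; a score is missing when 20% or more of the
items are missing (boundary inclusive), and below that threshold missing
items are mean-imputed from the subject's observed items — which leaves the
score equal to the observed-item mean. The power transform is
`[(y + 1)^lambda + 1] / lambda`, differing from the textbook Box-Cox form
only by an additive constant `2/lambda`, so all covariances, correlations
and variance components are identical under either; the natural domain is
y > -1. The exponent maximizes the normal profile log-likelihood (including
the Jacobian term) over a coarse 0.05 grid refined by bounded scalar
optimization; the search box [-6, 3] is a package choice that comfortably
brackets the estimates seen on scales of this kind (roughly -3.6 to -1.1).
After transformation every phenotype is divided by its standard deviation
*pooled over all twins and zygosities*, so subgroup variance differences
are retained and only the overall scale is set to about one. Degenerate
inputs (zero variance, fewer than 10 values) raise informative errors.

## Derived quantities

Standardized components divide each phenotype's component variances by its
A + D + E total — rater variance is excluded, so the reported a², d², e²
describe the phenotypes corrected for rater and sex effects. Component
correlation matrices normalize `Sigma_X` (and `Sigma_A + Sigma_D`) to unit
diagonal; entries whose component variance is zero are reported as missing,
not as zero. Covariance proportions are elementwise
`(Sigma_A + Sigma_D) / (Sigma_A + Sigma_D + Sigma_E)` and the E complement;
they sum to one exactly. Implied phenotypic correlations are computed two
algebraically identical ways — the path rule
`sqrt(h2_i) r_AD sqrt(h2_j) + sqrt(e2_i) r_E sqrt(e2_j)` and direct
normalization of the total covariance — and cross-checked to 1e-10 at every
call. When these chains are run from *printed* (3-decimal) summary tables,
reconstruction tolerances of ±0.0015 reflect rounding propagation, nothing
more. Reconstructed entries can straddle print (a worked-example value may
print as ~.340 where the table shows .341); unrounded values are reported.

## Factor models

The independent pathway model replaces a component's free Cholesky
covariance by two correlated common factors (hyperactivity-type and
inattention-type) with free loadings, plus per-phenotype residuals whose
cross-twin correlations are free per zygosity (absorbing residual genetic
and environmental variance). It is fitted by the same FIML engine with
correlations box-constrained to (-1, 1); non-convergence is a legitimate,
fully reported outcome, with the flattest likelihood directions named from
the Hessian's smallest eigenvector.

The confirmatory two-factor fit to a genetic correlation matrix estimates
loadings, a factor correlation and uniquenesses by minimizing the
normal-theory ML discrepancy (default); unweighted least squares on the
off-diagonal elements is available as an option. The two discrepancies
weight residuals differently and can prefer visibly different solutions on
the same matrix; ML was chosen as the default because it is what mainstream
SEM software computes on a correlation matrix and it reproduces the
published solution class on the embedded genetic matrix, whereas the ULS
optimum trades factor-correlation fit for loading fit. Point estimates
only — no standard errors are defined for a fit to a derived correlation
matrix. Solutions are sign-canonicalized (majority-positive loadings per
factor) and Heywood cases (|loading| > 1) are flagged but returned.

## Synthetic data

The generator is the model run forward: phenotype vectors are multivariate
normal with the group covariance of the pair's zygosity and teacher-sharing
status, sexes drawn at the study composition (default 1,593 pairs — 620 MZ,
973 DZ, 48.2% of DZ opposite-sex — with 57.2% of pairs sharing a teacher),
and blockwise MCAR missingness: the mother-rated block per twin, the
SWAN block per pair (it was collected only in sub-projects), the teacher
block jointly per twin. Default missing rates (31% / 69% / 56%) mirror the
registry study's sparsity. Optional raw-scale mapping pushes latent scores
through the inverse power transform and floors them at the censoring point,
yielding left-censored, positively skewed scales; values outside the image
of the forward transform are clamped to the floor and counted. Reverse
coding negates a phenotype (relevant to SWAN-like scales where high raw
scores are favourable).

What the generator does *not* emulate: item-level responses (phenotypes are
generated at subscale level), age effects, missingness that depends on the
phenotype (MCAR only, chosen because FIML is then unbiased and recovery
tests are clean), rater disagreement beyond the single shared-teacher
factor, and any non-normality on the transformed scale other than the
explicit raw-scale mapping. Passing recovery tests therefore demonstrate
correctness of the estimator under the model's own assumptions, not
robustness to their violation.

## Study sizes used in the checks

The recovery study uses 2,000 MZ + 2,000 DZ pairs at the published
generating magnitudes for the four hyperactivity phenotypes (two
mother-rated, two teacher-rated with rater factors), 57% teacher sharing,
and 10% blockwise MCAR missingness — a rate chosen once for the recovery
condition; the registry-like default rates are far sparser and would mostly
measure missing-data loss rather than estimator quality. LRT calibration
uses 400 null replicates of 600 + 600 univariate same-sex pairs. The
independent-pathway check uses 3,000 + 3,000 pairs with an exact two-factor
additive structure over eight phenotypes. An eight-phenotype version of the
recovery study is the same code path at a larger M and is not part of the
default suite.

## Known limitations

- The additive/dominance split is weakly identified in the classical
  design: its sampling error at a few thousand pairs is of order 0.05-0.1
  on the standardized scale (the h² sum is far better determined). The
  recovery check reports both the component-wise and the h² error.
- E carries measurement error, so "unshared environment" overstates true
  environmental influence.
- No liability-threshold/ordinal likelihoods, no WLS on polychoric
  matrices, no sibling-contrast (reciprocal pathway) models, no sex-specific
  multivariate variance components, no common pathway model.
- The C component shares the A cross-twin block's structure with weight 1;
  ACE and ADE cannot be distinguished within one fit (standard twin-design
  limitation), only compared across fits.
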