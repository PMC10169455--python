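# Methods

`ordmi` implements a complete simulation-and-analysis stack for missing
multilevel ordinal outcomes under informative cluster size (ICS): a
bridge-distribution data generator, proportional-odds regression by
cluster-weighted GEE (CWGEE), two multilevel multiple-imputation engines
(fully conditional specification and joint modelling, each with an optional
cluster-size covariate), Rubin pooling, and a Monte-Carlo study harness.
This note records the models, the numerical choices, and the places where
the design was genuinely open.

## Generative model

Each cluster i (a subject) has up to `max_size = 28` members (teeth).
Cluster-level covariates are X ~ N(0, 2²) and Z ~ Bernoulli(0.5).  Member
j's ordinal outcome (C categories) follows a conditional cumulative-logit
model with a member-level random effect b_ij:

    Pr(Y_ij <= c | b_ij) = expit{ b_ij + (eta_c + beta1 X_i + beta2 Z_i) / phi }

where b_ij has the bridge density

    f(b | phi) = sin(phi*pi) / ( 2*pi * (cosh(phi*b) + cos(phi*pi)) ),
    0 < phi < 1,

whose defining property is that integrating b out returns a marginal
proportional-odds model with the *same* coefficients (eta, beta).  This is
what makes the simulator's marginal contract testable: large-sample CWGEE
on full data recovers (eta, beta) exactly as specified.  Draws use the
closed-form quantile function

    Q(u) = (1/phi) * log( sin(phi*pi*u) / sin(phi*pi*(1-u)) ),

which we verified analytically against the density (f(Q(u)) Q'(u) = 1) and
numerically by quadrature.  The bridge variance is pi²(phi⁻² − 1)/3;
`phi = 0.5` by default.

The three auxiliaries M1–M3 are generated by the same mechanism with their
own cutpoints — defaults (−0.8, 0.4, 1.2), (−0.2, 1.0, 1.8),
(0.0, 1.2, 2.0) — and *share* b_ij and beta with the outcome, which is what
makes them informative in imputation.

**Within-cluster dependence.** The b_ij of a cluster are drawn from a
one-factor Gaussian copula with exchangeable correlation rho and bridge
marginals.  Because the bridge effect owns a share (1 − phi²) of the latent
logistic variance, setting `rho = tau / (1 − phi²)` makes the latent-scale
intraclass correlation equal the user-facing `icc = tau`.  Both phi and the
implied rho are configurable; tau in [0, 1 − phi²) is required for a valid
copula.

**Informative cluster size.** Cluster size is
n_i ~ Binomial(28, expit(nu * b̄_i)), with b̄_i the mean of all 28 potential
effects (this resolves the circularity of b̄_i depending on n_i); zero draws
are redrawn, and the first n_i members are retained.  nu > 0 links size to
latent health: healthier clusters (larger b, lower outcome categories) are
larger, so the Spearman correlation between n_i and the within-cluster mean
outcome is negative.

## Missingness

A logistic model per incomplete variable:
logit Pr(R=1) = alpha0 + alpha·(X, Z, Y, M1, M2, M3); R = 1 blanks the
value.  MCAR zeroes all six slopes, MAR zeroes the outcome slope, MNAR
keeps it.  alpha0 is calibrated by monotone root-finding so the Monte-Carlo
missing rate over pilot tables (30 by default) hits the target; outcome
targets are 20% or 50%, auxiliary targets (30%, 30%, 10%).  Auxiliary
missingness depends only on the fully observed X and Z, so it is always
ignorable.

The slopes themselves are a free design parameter.  We fixed
alpha = (0.1, 0.2, 0.3, 0.4, 0.4, 0.4): the common auxiliary slope 0.4 was
calibrated on a grid (N = 4000 clusters) so that the realized per-category
missing-rate profile at a 20% overall rate under MAR is approximately
(7%, 16%, 27%, 45%) across the four outcome categories — the gradient a
severity-driven missingness process produces (about 7/17/27/45 in the
motivating dental setting).  With these defaults the complete-case mean of
eta_1 stabilises around −0.26 at large N; the amount of attenuation is
sensitive to how much of the missingness gradient is member-specific rather
than cluster-level, so complete-case bias magnitudes should be read as
properties of these defaults.

## Analysis model: CWGEE

The C-category outcome is expanded into nested indicators U_c = 1(Y <= c)
and (eta, beta) solve

    sum_i (1/n_i) sum_j D_ij' V_ij^{-1} (U_ij − mu_ij) = 0

with working independence across members.  Across cutpoints the working
covariance is the *exact* covariance implied by the nesting,
Cov(U_c, U_c') = mu_c (1 − mu_c') for c <= c' (equivalently the correlation
sqrt(mu_c(1−mu_c') / ((1−mu_c)mu_c'))); an independence option exists for
sensitivity.  This choice has a convenient consequence used as a test
oracle: for independent single-member clusters the estimating function
equals the multinomial cumulative-logit score, so the fit coincides with
maximum likelihood to solver precision.

Solver: Fisher scoring with step-halving on the score norm, cutpoints
initialised at empirical cumulative logits, slopes at zero, tolerance 1e−8
on the largest update, at most 100 iterations; a trial step that makes the
working covariance numerically singular or the cutpoints non-monotone is
halved.  Robust variance: sandwich H^{-1} M H^{-1} with M built from the
weighted per-cluster estimating functions.  In complete-case analysis the
weights use the post-deletion cluster size (the natural CWGEE on the
reduced data); pre-deletion sizes can be supplied instead.

## FCS imputation

Each incomplete ordinal variable gets a random-intercept cumulative-probit
model, visited in the fixed order (Y, M1, M2, M3).  Identification: first
threshold fixed at 0, free intercept, residual variance 1; the other C−2
thresholds are sampled from their uniform full conditionals between
adjacent latent order statistics (bounded by ±8 when a category is empty,
with a warning).  Priors: flat on regression coefficients,
inverse-gamma(0.001, 0.001) on the random-intercept variance.  Other
ordinals enter as numeric scores; `include_cs` adds the cluster size n_i to
every linear predictor (the "+CS" variant).  The random-intercept SD can be
pinned (`sigma_u_fixed`), which reduces the sampler to single-level probit
augmentation — used by the tests to compare its stationary predictive
distribution against a direct probit fit.

## JM imputation

All four variables are represented jointly by latent normal columns, C−1
per variable, with the max-latent decoding rule (category c iff latent c is
positive and maximal; last category iff all negative).  This is a *nominal*
probit structure even though the variables are ordinal — deliberately so,
because it mirrors the latent-normal JM software whose behaviour the study
compares; its extra bias for ordinal outcomes is part of what the harness
measures.  The model is a multivariate random-intercepts regression with
per-column fixed effects (intercept, X, Z, optionally n_i).  The reference
formulation displays the fixed effects without a per-level subscript; we
give every latent column its own coefficients, without which the latent
means could not reproduce unequal category frequencies.

Within each variable's block of the residual covariance the diagonal is
fixed at 1 and off-diagonals at 0.5 (the nominal-probit identification
constraint); cross-variable blocks are sampled by random-walk Metropolis on
the free elements, with non-positive-definite proposals rejected (we use
rejection rather than projection-to-PSD because projection would break
detailed balance) and the step size adapted during burn-in toward 20–40%
acceptance.  Random-intercept covariance: inverse-Wishart with identity
scale and df = L + 2 (L latent columns), drawn by Bartlett decomposition.
Latent truncation for observed categories is enforced by element-wise Gibbs
within the row, so the decoding contract holds at every sweep; each saved
copy re-checks it and fails loudly on violation.

## Pooling and metrics

Classic Rubin rules: Q̄, W̄, B, T = W̄ + (1 + 1/M)B, per-parameter
df = (M−1)(1 + W̄_kk/((1+1/M)B_kk))², t-based intervals (normal when B = 0);
an optional Barnard–Rubin small-sample df is off by default since the
pooled covariances are large-sample sandwich objects.  The harness computes
six metrics per parameter, method and scenario: mean estimate, mean robust
SE, empirical SE, mean relative bias (%), 95% coverage (%, normal critical
value 1.96), and MSE.  Relative bias is reported as NaN when the true value
is zero (absolute bias is always available).  Per-method failures exclude
that replicate for that method only, with counts reported.

## Chain lengths and problem sizes

The reference scale is M = 5 imputations, 4,000 burn-in sweeps and 1,000
sweeps between saved imputations ("full" preset).  Because the imputation
models here are small (≤ 7 regression coefficients, ≤ 2 free thresholds per
variable; 12 latent columns for JM), the chains reach stationarity far
sooner, and the package ships two shortened presets used throughout the
test suite and the acceptance script: "reduced" (500 / 200) and "fast"
(300 / 100).  Monte-Carlo arms use 40–1,000 replicates depending on the
cost of the method being exercised (full-data and complete-case arms at
R = 1,000; MI arms at R = 40–100; directional comparisons at R = 50–100,
below the R = 200 a larger study would use).  Determinism: every replicate
draws its generator from SeedSequence([scenario seed, purpose, replicate]),
so results are bit-reproducible and independent of execution order.

## What the generator does and does not emulate

It reproduces the structural features that matter for the methods under
study: ordinal outcomes clustered in unequal, outcome-informative cluster
sizes; auxiliaries correlated with the outcome through a shared
member-level effect; severity-graded missingness.  It does not emulate
level-2 missingness, monotone/longitudinal dropout, member-level
covariates, three-level structure, or real dental-registry idiosyncrasies
(digit preference, examiner effects).  Passing tests therefore support the
correctness of the estimators and samplers under this generative family,
not their behaviour on any particular real dataset.

## Known limitations

- Complete-case bias magnitudes depend on the unidentified missingness
  slopes; only their calibrated per-category profile is matched to the
  reference setting, so CCA means should be compared loosely.
- The FCS and JM engines target distribution-level agreement with the
  software they emulate, not draw-level agreement; priors and threshold
  update schemes differ in unpublished details.
- The exchangeable-bridge construction via a Gaussian copula is one of
  several possible; the mapping rho = tau/(1 − phi²) is exact for the
  latent variance decomposition but the copula correlation is not exactly
  the Pearson correlation of the bridge margins.
- Coverage uses normal critical values throughout; at M = 5 and N = 50 a
  t reference would change coverage by well under the Monte-Carlo noise.
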