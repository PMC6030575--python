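# Methods

## The joint measurement model

Two instruments measure the same construct at different cadences: a
2-item daily depressed-mood rating (responses nominally 1–5) collected
for up to 14 days, and a 9-item questionnaire (items nominally 0–3)
completed at an anchor week.  The model couples a two-level factor
structure for the daily items with a single-level structure for the
questionnaire:

* daily item a, person j, day i:
  `y_aji = nu_a + lambda_b * eta_bj + lambda_w * eta_wij + eps_b,aj + eps_w,aji`,
  where `eta_bj` is the person's stable severity, `eta_wij` a day factor
  shared by both items, `eps_b,aj ~ N(0, theta_b,a)` a person-level item
  residual (constant across days), and `eps_w,aji ~ N(0, theta_w,a)` a
  day-level residual;
* questionnaire item k: `z_kj = tau_k + lambda_k * xi_j + delta_kj`.

Identification fixes all latent means at 0 and variances at 1, and — with
only two daily indicators — equates the daily loadings across items
within each level.  `corr(eta_b, xi) = r` is free.  By default the two
daily items keep separate intercepts and residual variances; an
`equal_daily_item_params` switch equates them (the published table shows
identical values for the two items, which could be either rounding or a
constraint — we default to the weaker assumption and expose the switch).

Item responses are treated as continuous (normal-theory ML).  This
matches the scale of the published estimates; threshold/categorical
estimation is out of scope.

## Estimation

Integrating the latents gives, for person j with n_j daily days, a
multivariate normal over the stacked `(9 + 2 n_j)`-vector with

    Cov(y_ji, y_ji') = Sigma_b                (i != i')
    Cov(y_ji, y_ji ) = Sigma_b + Sigma_w
    Cov(z_j)         = Lambda Lambda' + Theta_9
    Cov(z_j, y_ji)   = Lambda r lambda_b'

`Sigma_b = lambda_b lambda_b' + Theta_b`,
`Sigma_w = lambda_w lambda_w' + Theta_w`.  The log-likelihood is the sum
of these person densities (full-information ML), so unbalanced cluster
sizes are handled exactly rather than through a balanced two-matrix
approximation.  A person missing a whole block contributes the marginal
density of the observed block; a daily row or questionnaire block with a
missing item is dropped (block-level, not item-level, missingness
handling).

Because the implied covariance depends on a person only through
(n_j, blocks observed), persons are grouped into patterns and the
likelihood is evaluated from per-pattern sufficient statistics
(sum of vectors, sum of outer products): one Cholesky factorization per
pattern per evaluation, with cost independent of the number of persons.
Tests verify this against a dense multivariate-normal oracle at 1e-8.

Optimization: L-BFGS-B on a transformed scale (log variances, atanh
correlation), gradient max-norm tolerance 1e-6, at most 500 iterations,
numerical gradients.  Starting values: loadings 0.5, intercepts at item
means, residual variances at half the item variances, r = 0; an optional
multistart adds perturbed restarts.  `|r| > 0.995` raises a boundary
warning.  Standard errors come from the inverse of a central-difference
Hessian on the transformed scale, delta-method mapped back; sandwich
(robust) SEs are not implemented.

The saturated model frees all 11 person-level means, the full 11x11
person-level covariance (Cholesky-parameterized) and the 2x2 day-level
covariance (80 parameters); the independence baseline keeps only means
and variances (24).  `chi2 = 2(ll_sat - ll_model)`,
`df = 80 - 36 = 44`, and CFI/TLI are the usual incremental indices;
RMSEA uses N = number of persons (persons are the independent sampling
units, so the 545-scale N, not the 2992 observations).

## Reliabilities

With unit latent variances, composite (omega) reliability of an
unweighted item sum is `(sum lambda)^2 / [(sum lambda)^2 + sum theta]`,
applied to the questionnaire block and to the within-level daily block.
The person-mean daily reliability over `n_bar` days divides the whole
within-level composite variance (common + residual) by `n_bar`:

    rho(n_bar) = (sum lambda_b)^2 /
                 [(sum lambda_b)^2 + sum theta_b
                  + ((sum lambda_w)^2 + sum theta_w)/n_bar]

This is the unique standard formula that reproduces the published
between-person value from the published parameter table with the
arithmetic-mean cluster size (2992/545 = 5.49); a harmonic-mean option is
provided because with unbalanced clusters the harmonic mean is the exact
choice for the reliability of equally-weighted person means.  rho is
strictly increasing in `n_bar` and bounded by the between-level omega.

## Invariance testing

Binary demographic splits (gender, age band, minority status) are
compared by a likelihood-ratio test of:

* unconstrained — all measurement parameters free per group (two
  independent fits);
* constrained — loadings, intercepts and residual variances shared;
  latent variances re-freed in the second group (once loadings are in a
  common metric, group differences in latent spread are estimable);
  latent means fixed at 0 in both groups; r free per group.

With the joint model this gives df = 2*36 - (35 + 2 + 3) = 32, counted
from the parameter-vector lengths, never hard-coded.  A caveat of this
convention: a *proportional* shift of one group's loadings is largely
absorbed by that group's re-freed latent variance, so the LRT has little
power against it; intercept or residual shifts are not absorbable.  The
test suite's planted-effect check therefore shifts intercepts.

p-values are chi-square upper tails, reported to 3 decimals, with no
multiple-testing correction.

## Outcome prediction

Each person's daily composite (mean of the two items) over the 14-day
window is summarized by mean, sample SD, min, max, and the least-squares
slope per calendar day (gaps matter; SD and slope are missing with fewer
than two rated days).  Four models predict the week-8 questionnaire and
disability sums: (1) week-4 questionnaire sum; (2) daily mean; (3) both;
(4) daily mean + slope + max + min + SD.  The composite is the item
*mean* (1–5 scale) rather than the sum, so slope and SD are in per-item
units; this affects coefficient magnitudes but not R².

Both equations are estimated jointly by seemingly unrelated regression:
per-equation OLS, residual covariance (ML denominator n), then one joint
GLS step; optional iteration to convergence (which cannot decrease the
concentrated Gaussian likelihood).  All four models use identical
regressors in the two equations, so point estimates equal per-equation
OLS (Kruskal); the SUR machinery still yields the cross-equation residual
covariance and supports unequal designs.  R² is `1 - SSR/SST` about the
outcome mean; persons missing any required predictor or either outcome
are dropped listwise, which makes the analysis N differ across models
(model 4 additionally loses single-rating persons).

## The synthetic cohort generator

Defaults emulate a 545-person community study of daily mobile depression
monitoring and are the package's reference study conditions:

* ratings per person: the study's empirical 1..14 distribution — exact
  counts in fixture mode (545 persons, 2992 ratings, mean 5.49), or i.i.d.
  draws from its proportions for other sizes;
* day placement: uniform without replacement in the 14-day window
  preceding the anchor day (the source distribution of placements is
  unknown; uniform is the maximally uninformative choice).  The
  likelihood is exchangeable in day order, so placement only affects the
  slope/SD summaries;
* latents: bivariate standard normal, r = 0.80;
* measurement: the published loadings/intercepts/residual variances;
* baseline severity: normal with SD 5.0 truncated below at the
  eligibility floor 5, its pre-truncation mean calibrated by root-finding
  so the post-truncation mean is 13.9; clipped to [0, 27].  Baseline is
  generated independently of the week-4 latent structure (it is used only
  descriptively);
* group labels: independent Bernoulli draws (78.3% women, 38.1%
  minority, 6.1% aged 55+); optional per-group parameter offsets
  (default zero, so invariance holds unless planted);
* week-8 outcomes: bivariate linear in the week-4 questionnaire sum with
  correlated Gaussian errors; the residual variances are solved from
  `R^2 = b^2 var(x) / (b^2 var(x) + sigma^2)` with the model-implied
  `var(x) = (sum lambda)^2 + sum theta = 29.41` so the population R²
  equals 0.49 (symptoms, slope 0.7) and 0.37 (disability, slope 2.7);
  residual correlation 0.4; an optional daily-mean coefficient (default
  0) plants incremental predictive value; 35% of week-8 rows are deleted
  completely at random (matching the scale of the study's week-8
  attrition, whose mechanism is unknown).

Continuous mode (default) leaves responses on the linear scale so sample
moments converge to model-implied moments and refits recover generating
parameters without attenuation; `discretize` rounds and clips to the
Likert ranges, which attenuates covariances (verified in tests) — it
emulates the look of real data but is not used for recovery checks.
Outcome sums are not clipped to their nominal scale ranges (clipping
would distort the calibrated R²).

What passing tests therefore show: the estimators are correct for data
that satisfy the model (Gaussian, linear, MCAR attrition, invariant
groups unless planted).  They cannot show robustness to categorical item
response processes, informative missingness, response-time effects, or
non-normal severity distributions — none of which the generator emulates.

## Numerical choices and scales

* Likelihood evaluations guard non-positive-definite proposals (the
  optimizer sees a large finite penalty; the public API raises a
  descriptive error).
* Saturated/baseline optimizations start from ANOVA-style moment
  estimates (pooled within covariance; person-level covariance minus the
  within correction, eigenvalue-clipped to be positive definite).
* The LRT raises a refit signal if the chi-square is below -1e-4;
  smaller negatives are clipped to 0.
* Simulation sizes used by the test and acceptance runs: moment checks at
  n = 20 000 (2% tolerances), latent-correlation recovery at the study's
  own 545-person scale over 20 seeds (median within 0.03), SE-coverage
  recovery at n = 2000 over 20 seeds, null LRT calibration over 200
  replicates of a reduced daily-only two-group design (60 persons/group,
  3-7 days each) tested against chi-square(6) by Kolmogorov-Smirnov.
  These sizes keep every check at desk scale while leaving Monte-Carlo
  error well inside the asserted tolerances.

## Known limitations

* No sampling weights, no three-level structure, no Bayesian or robust
  (scaled chi-square) estimation; printed fit indices from studies using
  a scaled chi-square will not match exactly.
* Item-level missingness within a block drops the affected row/block
  rather than being integrated over.
* The invariance convention (df = 32) is one of several defensible
  choices; the per-group parameter counts are exposed in the output so
  alternatives can be audited.
* k-group invariance (k > 2) and partial-invariance search are not
  implemented.
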