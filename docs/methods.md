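# Methods

## Model

`mgcfa` fits congeneric confirmatory factor models with a mean structure to
one or more groups of respondents. For group *g* with *p* items and *m*
factors,

    Sigma_g = Lambda_g Phi_g Lambda_g' + diag(Theta_g)
    mu_g    = nu_g + Lambda_g kappa_g

where `Lambda` holds the loadings (each item on exactly one factor), `nu`
the item intercepts, `Theta` the residual ("uniqueness") variances, `Phi`
the factor covariance matrix and `kappa` the factor means. The latent
metric is set by marker scaling: the first listed item of each factor has
its loading fixed to 1, so factor variances and means are expressed in that
item's units. An optional second-order layer replaces the free `Phi` by
`Gamma phi2 Gamma' + diag(D)` with the second-order variance `phi2` fixed
to 1, all second-order loadings and disturbances free. This identification
gives 166 df for the single-group 20-item model; published tables that
print 167 for a comparable model rest on an unstated alternative
identification, and no attempt is made to force that count.

Estimation minimizes the normal-theory ML discrepancy

    F = sum_g w_g [ ln|Sigma_g| + tr(S_g Sigma_g^-1) - ln|S_g| - p
                    + (xbar_g - mu_g)' Sigma_g^-1 (xbar_g - mu_g) ]

with weights `w_g = (n_g - 1)/(N - G)` and test statistic `T = (N - G) F`.
Different SEM programs use slightly different N-vs-N-1 conventions; since
the convention cancels out of df counts and of between-model index deltas,
absolute chi-square values from other software are not reproduced and are
not treated as comparable. Likert items are treated as continuous, which is
the convention of the analysis this package reproduces; no polychoric or
robust variants are provided.

Cross-group equality constraints are realized structurally: equated
parameters map onto a single free parameter shared by all groups, so
constraints hold exactly rather than through penalties.

## Numerical choices

- Optimizer: L-BFGS-B on transformed parameters — log scale for variances
  (uniquenesses, disturbances) and a Cholesky factorization with
  log-diagonal for `Phi` — so every iterate yields a positive-definite
  implied covariance. Gradients are analytic; the finite-difference
  agreement is ~1e-9 relative.
- Convergence: `ftol` 1e-13, gradient norm tolerance 1e-7; a fit is flagged
  non-converged otherwise. On just-identified models the solution matches
  the closed-form tetrad expressions to better than 1e-5.
- Start values: markers 1; other loadings from marker-covariance ratios
  `s_im / s_mm`; intercepts at observed means; uniquenesses at half the
  observed variances; `Phi` at half the marker-item covariance block;
  factor means 0. Refits inside the invariance ladder warm-start from the
  previous step's solution.
- Heywood handling: uniquenesses are floored at 1e-6 via an optimizer
  bound; estimates at the floor are reported in the fit's diagnostic list.
  No constraints are juggled after the fact.
- Standard errors: inverse of the numerically differentiated Hessian of
  `(N - G)/2 * F` at the optimum, delta-method-mapped back to the raw scale
  for log-parameterized variances. Whether a given SEM program uses
  expected or observed information is generally unknowable from its output,
  so z statistics are validated by simulation coverage, not against
  published tables.

## Invariance ladder and decision rules

Four nested multi-group models run in order: configural (same pattern,
all parameters group-specific, factor means fixed to 0 everywhere), metric
(loadings equated), scalar (loadings and intercepts equated; factor means
free in non-reference groups), uniqueness (residual variances additionally
equated). Degrees of freedom are counted analytically and independently of
the optimizer; for the 20-item four-factor battery the ladder is
328/344/360/376-with-inherited-releases, and the partial models with the
released items of the reproduced analysis give 358 and 373.

Each step is compared with the previous *accepted* (possibly partial)
model using change-in-fit rules: dCFI < 0.01 and dRMSEA < 0.015, both
required by default. Chi-square differences are reported but never drive
decisions: with thousands of respondents they are essentially always
significant. On rejection, the partial-invariance search refits the step
once per releasable candidate and frees the constraint with the largest
chi-square gain, repeating until the deltas pass or candidates are
exhausted. Exact refits are used instead of modification indices (the
models are small and refits cost ~50 ms); ties are broken by item order.
Marker loadings are never released (the latent scale must stay anchored);
intercept releases are allowed for any item — including markers — provided
the factor keeps at least one equated intercept, which is what keeps the
latent mean difference identified. Items whose intercepts were released at
the scalar level keep their uniquenesses unconstrained at the uniqueness
level, matching the df arithmetic of the reproduced analysis.

Fit indices: RMSEA uses the `sqrt(G)` multi-group multiplier and a 90% CI
from the noncentral chi-square (lower bound where the observed T sits at
the 95th percentile, upper at the 5th; 0 when T <= df). CFI uses the
guarded incremental definition against the independence-with-free-means
baseline, whose ML solution is closed-form; NNFI is reported unclipped and
NaN when the baseline ratio T_b/df_b <= 1. AIC is `T + 2q`. Because the
RMSEA multiplier and chi-square conventions vary across programs, these
indices are consumed as within-run deltas; their absolute values are not
comparable across software.

## Latent mean effects and reliability

With (at least partial) scalar invariance, the non-reference group's factor
means `kappa` are latent mean differences. Hancock's d standardizes them by
the pooled latent SD with (n-1) weights:

    d = (kappa_2 - kappa_1) / sqrt(((n1-1) sd1^2 + (n2-1) sd2^2)/(n1+n2-2))

The (n-1)-weighted pooling reproduces the published worked examples to
+-0.001; unweighted pooling does not. Latent SDs are square roots of the
model-implied factor variances per group. McDonald's omega per factor is
`(sum lambda)^2 phi / ((sum lambda)^2 phi + sum Theta)`. Published omega
values for the CES-D samples stem from per-sample fits of raw data that is
not available, so they serve as context only and are not reproduced.

## Synthetic data generator

The generator emulates the two-elderly-sample CES-D study conditions: two
groups of sizes 4903 and 1903, 20 items, four factors (somatic complaints
7 items, depressive affect 7, positive affect 4, interpersonal problems 2),
parameters set to the published unstandardized estimates. The groups share
all loadings, differ in the intercepts of Failure and Good and in the
uniquenesses of Depressed, Failure, Fearful, Good and Dislike, and the
second group's latent means are (-0.261, -0.259, -0.125, -0.323) with
latent SDs (0.482, 0.570, 0.354, 0.574) vs (0.324, 0.318, 0.329, 0.184).
Respondents are drawn as `eta ~ N(kappa, Phi)`, `e ~ N(0, diag(Theta))`,
`y = nu + Lambda eta + e`, with under-1% MCAR missingness by default;
summaries use pairwise-available-case means and covariances with
(n_pair - 1) denominators (no FIML — at this missingness level the
difference is negligible and the reproduced analysis used available-case
moments).

Latent factor correlations are not published. The default is a mildly
heterogeneous matrix (SOM-DEP 0.65, DEP-INT 0.55, DEP-POS 0.50, SOM-POS
0.45, SOM-INT 0.40, POS-INT 0.35, all in the positive orientation after
reverse coding). A uniform correlation was rejected deliberately: a
constant correlation matrix is exactly representable by a second-order
factor, which would make the four-factor and second-order structures
empirically indistinguishable in model-comparison exercises. This matrix
is an implementation assumption, not a published value, and is
configurable.

Continuous responses are the default for estimation work (the reproduced
analysis treats the 4-point items as continuous). Optional Likert output
discretizes through thresholds at the quartiles of each item's
reference-group marginal. The generator does **not** emulate ordinal
coarseness effects on ML estimates, response styles, MNAR missingness, or
non-normal latent distributions — so passing recovery tests demonstrate
correctness of the estimator under the stated model, not robustness to
those real-data features.

## Problem sizes used by the test and acceptance runs

Parameter recovery runs one draw at the full study sizes (4903, 1903).
Planted non-invariance detection uses 100 replicates at n = (2000, 2000),
rotating single intercept shifts of 0.6 and uniqueness shifts of 0.5 over
ten items; a replicate counts as a success when the corresponding ladder
step is rejected and the planted parameter is the first released. Null
calibration uses 50 fully invariant replicates at n = (1000, 1000). The
monotonicity audit fits the full ladder on two datasets of n = (800, 700)
and (2500, 1500).

## Known limitations

- Recovery precision is bounded by the design itself: the positive-affect
  factor is anchored by a weak marker (standardized loading 0.32,
  uniqueness 1.20), so the remaining positive-affect loadings have
  sampling SDs near 0.06-0.10 even at n = 4903/1903. Single-draw recovery
  of those loadings to better than +-0.05 is not achievable by any
  estimator under these conditions; intercepts, uniquenesses and latent
  mean effects are recovered well inside their tolerances.
- Loading shifts are hard to detect with the dCFI/dRMSEA rules when the
  factor variance is small (a 1.0 shift on a positive-affect loading
  passes the metric cutoffs at n = 2000 per group); this mirrors the known
  insensitivity of those rules, not an implementation defect.
- No WLSMV/polychoric estimation, no Satorra-Bentler corrections, no FIML,
  no longitudinal invariance, no cross-loadings or correlated residuals.
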