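# Methods

## Model

Two-level latent covariate model with J groups of equal size n. The
predictor decomposes into independent normal components
`X_ij = mu_x + U_j + R_ij` with `Var(U) = sigma2_bx`, `Var(R) = sigma2_wx`;
the outcome follows
`Y_ij = gamma + beta_b U_j + E_j + beta_w R_ij + eps_ij` with group-level
residual variance `sigma2_eb` and individual-level residual variance
`sigma2_ew`. The target parameter is the between-group slope `beta_b`,
the effect of the *latent* group mean of X on the group-level part of Y.
Intercepts and `mu_x` default to zero throughout the simulator: they cancel
in every slope estimator.

Parameterizations are ICC-indexed under a unit-total-variance convention
for both variables: `sigma2_bx = icc_x`, `sigma2_wx = 1 - icc_x`, and the
residual variances solve

    sigma2_eb = icc_y - beta_b^2 * icc_x
    sigma2_ew = (1 - icc_y) - beta_w^2 * (1 - icc_x).

A design cell is feasible iff both are nonnegative; the feasibility check
names the binding constraint. This is why a large between slope is
incompatible with a modest outcome ICC (e.g. `beta_b = 0.7` at
`icc_x = 0.5` would need a negative `sigma2_eb` when `icc_y = 0.2`, while
`beta_b = 0.6` is feasible).

## Sufficient statistics and ML

For balanced data the ANOVA estimators use denominators `J - 1` (variance
and covariance of observed group means) and `J(n - 1)` (pooled within
(co)variance); the latent-aggregation correction subtracts the within mean
square over n:

    s_bx  = Var_hat(xbar_j)      - s_wx  / n
    s_bxy = Cov_hat(xbar, ybar)  - s_wxy / n

With this convention `E[s_bx] = sigma2_bx` exactly (verified by Monte Carlo
in the tests). `beta_hat_ML = s_bxy / s_bx`, with no truncation of negative
`s_bx`: the resulting instability in small, low-ICC samples is a real
property of ML that the simulation study must reproduce.

## Exact distributional representations

Both `s_bx` and `s_bxy` are quadratic forms in the underlying standard
normals. `build_quadform_reps` constructs the coefficient matrices
explicitly (dimension `2J + 2Jn`) and eigendecomposes them (symmetrized;
eigenvalues below `1e-10` of the largest treated as zero). The `s_bx` form
has `J - 1` positive eigenvalues `sigma_mxx / (J - 1)` — where
`sigma_mxx = sigma2_bx + sigma2_wx / n` is the variance of one group mean —
and `J(n - 1)` negative eigenvalues `-sigma2_wx / (n J (n - 1))`; the
subtraction that makes the estimator unbiased necessarily makes the form
indefinite. Equal-eigenvalue blocks map to scaled gamma variables
(`m` chi-square(1) terms of weight `w` -> `Gamma(m/2, 2w)`), representing
each estimator as a difference of gamma sums. Closed-form Wishart moments
give, independently of any matrices,

    Var(s_bx)        = 2 sigma_mxx^2/(J-1) + 2 sigma_wxx^2/(n^2 J(n-1))
    Var(s_bxy)       = (sigma_mxx sigma_myy + sigma_mxy^2)/(J-1)
                       + (sigma_wxx sigma_wyy + sigma_wxy^2)/(n^2 J(n-1))
    Cov(s_bxy, s_bx) = 2 sigma_mxx sigma_mxy/(J-1)
                       + 2 sigma_wxx sigma_wxy/(n^2 J(n-1))

and the tests verify these against the eigenvalue trace identities and
against two-path Monte Carlo (quadratic-form sampling vs. direct data
simulation).

## Approximate distribution of the slope estimators

The shrinkage estimator is `beta_hat_B = s_bxy / D` with
`D = lam * s_bx + (1 - lam) * prior_loc`. Its exact moments do not exist —
D crosses zero with positive probability — so the analytic engine uses a
deliberate light-tail approximation, constructed as follows:

1. decompose `s_bxy = beta_star * s_bx + C` with
   `beta_star = Cov(s_bxy, s_bx)/Var(s_bx)`, so C is uncorrelated with D;
   treat C as independent of D (the approximation step);
2. match D with a gamma distribution on its exact mean and variance, with
   the shape floored at `(J - 1)/2` — the between-group chi-square degrees
   of freedom that drive D's randomness. The floor keeps the ML corner
   (`lam = 1`) finite and is the analogue of approximating a ratio by an F
   distribution with `df2 = 2k` denominator degrees of freedom;
3. inverse-gamma moments of `1/D` then give mean, variance,
   `MSE = variance + (mean - beta_b)^2` (exactly, by construction) and
   `SE = sqrt(variance)`.

Moments are flagged *undefined* when the matched shape is <= 1 (mean) or
<= 2 (variance); at `J = 5` the ML point itself has no second moment under
the floor, mirroring the instability the shrinkage route repairs. In
stable regimes (e.g. `J = 40`, `icc_x = 0.5`) the approximate MSE tracks
simulation to ~10-15%; in the extreme small-J/low-ICC corner it is best
read as a finite, smooth stand-in for an infinite exact moment — which is
precisely what makes it usable as a minimization objective.

## Estimated MSE and the plug-in

The estimated MSE substitutes parameter *estimates* into the analytic MSE:
`sigma2_bx -> max(s_bx, 0)`, `beta_w -> s_wxy/s_wx`, residual variances
clipped at zero, and the unknown `beta_b` replaced by the ML estimate
(empirical Bayes; the true value can be supplied as a simulation-only
benchmark). Two details matter for robustness, both active exactly in the
unstable regime and asymptotically inert:

- the plug-in slope enters the *moment structure*, not only the bias
  target. When the plug-in is extreme (the regime where ML explodes) the
  entire objective then scales with its square, so the selected prior
  stabilizes instead of chasing the extreme value;
- the plug-in slope is projected onto a sampling-aware feasible range
  `beta^2 (max(s_bx,0) + 2 SD(s_bx)) <= max(s_by, 0)`: a slope estimate is
  only accepted as a working truth if it remains feasible at an upper
  confidence bound of the between variance, which prevents a noise-level
  `s_bx` from attributing all between-group outcome variance to the slope.

## Grid search

Grid over `lam` (uniform on (0, 1], 100 points, always containing the ML
special case `lam = 1`, i.e. `eps = 0`) times `prior_loc` (uniform on
`[0, d]`, 100 points) with `d = 5 * SD(s_bx)` from the derived
distribution (moment-based fallback at degenerate inputs). Grid points
with undefined moments, or where the actual estimator's denominator would
be non-positive, are excluded, never imputed; if everything is excluded the
search falls back to ML with a warning. Ties break toward least shrinkage
(largest `lam`, then smallest `prior_loc`). The returned estimated MSE is
by construction no larger than at the ML point. A boundary-hit flag
reports optima on the region edge — frequent in very low-ICC cells, where
the objective is nearly flat beyond the boundary (enlarging d moves the
optimum slightly but changes RMSE by under 5%); the bound is kept at its
5-SD default. The search is a local-optimum procedure by design; the grid
resolution (default 100 x 100) is a config knob.

## Standard errors

Analytic SE from the approximate distribution at the selected prior, or a
delete-d jackknife with groups as the resampling unit:
`SE^2 = (J-d)/(d m) * sum_S (theta_S - mean)^2` over deletion sets S.
Default `d = max(1, floor(sqrt(J)))`; full enumeration when
`C(J, d) <= 10,000`, otherwise 10,000 seeded random deletion sets. For a
linear statistic with d = 1 this reproduces the classic closed form. The
jackknife is the recommended choice in small samples.

## Synthetic data and the study engine

`generate_dataset` draws the model exactly as parameterized above; RNG
streams are counter-based (root seed, scenario key, replication index), so
scenarios and replications are independent, order-invariant and
parallelizable, and every dataset is bit-reproducible. The factorial
design enumerates `icc_x in {0.05, 0.1, 0.3, 0.5}`, `J in {5, 10, 20, 30,
40}`, `n in {5, 15, 30}`, `beta_b in {0.2, 0.5, 0.6}`,
`beta_w in {0.2, 0.5, 0.7}` at `icc_y = 0.2`: 540 cells, all feasible
under the unit-variance normalization; infeasible user-supplied cells are
skipped with a warning record.

The study engine scores RMSE and relative bias (undefined at
`beta_b = 0`, reported as NaN with a flag) with delta-method Monte-Carlo
SEs. ML failures/extremes are included as computed — they are the
phenomenon — with an off-by-default winsorizing diagnostic. Default
replications are 5,000 per cell; the bundled tests and the acceptance
script use 300-2,000 replications and scaled-down cell subsets so the full
suite runs in minutes on one CPU.

What the generator does *not* emulate: unbalanced designs (unbalanced
fixtures are made by deleting rows, as the balancing procedure assumes),
non-normal components, measurement error beyond the latent-mean structure,
and three-level or longitudinal nesting. Passing tests therefore speak to
the model's own sampling regime, not to robustness against
misspecification.

## Known limitations

- The analytic distribution is a two-moment approximation; its MSE is an
  approximation target, not an exact risk. Where the exact moments do not
  exist the reported values are finite by construction.
- The true-slope benchmark variant retains a small real advantage over the
  ML-plug-in variant in the hardest cells with more groups (about 0.03-0.04
  RMSE on ~0.48 at `J = 20`, `n = 5`, `icc_x <= 0.1`): with that many
  groups the data begin to carry resolvable signal that only the oracle
  can use perfectly. The two variants are indistinguishable at `J <= 10`.
- Balanced-design theory only; the deletion-based balancing step discards
  data and aborts beyond a 20% deletion fraction (threshold configurable).
- The grid search finds a local optimum on a bounded region; no global
  optimization guarantee is intended.
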