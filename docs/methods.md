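# Methods

## Model and estimands

`stdcontrast` works with the fixed-effects ANCOVA model

    Y_ij = mu_i + sum_{k=1}^P beta_k X_kij + eps_ij,   eps_ij ~ N(0, sigma^2),

for i = 1..G groups and j = 1..N_i subjects. The estimand is a standardized
linear contrast of adjusted group means,

    psi* = psi / sigma,   psi = sum_i c_i mu*_i = sum_i c_i mu_i,   sum_i c_i = 0,

where mu*_i is the expected response of group i evaluated at the grand
covariate means. Standardizing by the error standard deviation makes the
contrast comparable across studies whose response scales differ.

Least squares on the pooled within-group centered covariates gives slopes
`beta_hat = S_XX^{-1} S_XY`, intercepts `mu_hat_i`, the error variance
`sigma_hat^2 = SSE / nu` with `nu = N_T - G - P`, and the contrast estimate
`psi_hat`. Its variance is `sigma^2 V` with

    V = a + Q / (N_T - G),   a = sum_i c_i^2 / N_i,
    Q = (sum_i c_i xbar_i)' V_XX^{-1} (sum_i c_i xbar_i),

where `Q` measures the sample disparity of the contrasted covariate means.
The plug-in estimator `psi_hat* = psi_hat / sigma_hat` is biased upward;
the correction factor

    u(nu) = Gamma(nu/2) / { (nu/2)^{1/2} Gamma((nu-1)/2) }

(the same correction that turns Cohen's d into Hedges' g) is computed on
the log-gamma scale and requires `nu > 1`.

## Interval estimators

The observed statistic `T_O = psi_hat*/V^{1/2}` follows a noncentral
t(nu, lambda) law with `lambda = psi*/V^{1/2}`. Three intervals for `psi*`
are provided:

* **Exact (noncentrality inversion).** Each limit is `lambda V^{1/2}` where
  `lambda` solves a tail equation `P{t(nu, lambda) <= T_O} = 1 - alpha_1`
  (lower) or `= alpha_2` (upper). The CDF is continuous and strictly
  decreasing in the noncentrality, so each root is unique; brackets start
  from the closed-form zero-statistic anchor and expand geometrically, and
  a bracketed derivative-free solve finishes at |CDF error| <= 1e-10 with a
  1e-8 self-check. Tail targets below 1e-12 switch to the survival-function
  parameterization. Equal tails `alpha_1 = alpha_2 = alpha/2` are the
  two-sided default; one-sided forms are exposed.
* **Asymptotic.** `psi_hat* -/+ z_{alpha/2} (V + psi_hat*^2/(2 nu))^{1/2}`,
  from the large-sample normal law of the standardized estimator.
* **Direct division.** `psi_hat* -/+ t_{nu,alpha/2} V^{1/2}`, the
  unstandardized t limits divided by `sigma_hat`. It is equidistant where
  the exact interval is not, and the coverage simulations reproduce its
  systematic undercoverage for |psi*| >= 1.

Internal values are full precision; rounding to four decimals happens only
at presentation.

## Precision analysis under random covariates

For planning, covariates are treated as stochastic:
`X_ij ~ N_P(mu_Xi, Sigma_X)`. Then `V = a (1 + b F_X)` with
`b = P/(nu+1)` and `F_X ~ F(P, nu+1, xi)`, where `xi = theta/a` and

    theta = (sum_i c_i mu_Xi)' Sigma_X^{-1} (sum_i c_i mu_Xi)

is the population covariate-disparity index (zero under randomization with
identical group covariate means). All precision results depend on
`(mu_Xi, Sigma_X)` only through `theta`; `CovariateModel` accepts either
parameterization. The scaled quantity `f^2* = theta/a*` plays the role of
a signal-to-noise ratio for choosing disparity magnitudes.

Both exact-interval limits scale by `V^{1/2}`, so the width factorizes as
`W = V^{1/2} d(T)`, with `d(t)` the width of the noncentrality interval at
observed statistic `t` — a V-free function of `(nu, alpha)` that is
symmetric in `t` with minimum `d(0) = 2 z_{alpha/2}`. The two precision
criteria are

    Omega = E_F[ V^{1/2} E_T[ d(T) ] ]          (expected width)
    Gamma = E_F[ P_T{ d(T) <= omega/V^{1/2} } ]  (assurance of width <= omega)

with `T | F_X ~ t(nu, psi*/V^{1/2})`. The covariate-omitting (approximate)
variants replace `V` by `a` and drop the outer expectation:
`Omega_a = a^{1/2} E[d(T)]` and `Gamma_a = P{d(T) <= omega/a^{1/2}}` with
`T ~ t(nu, psi*/a^{1/2})`. They are retained for comparison; the numerical
study they support shows they underestimate widths and required sizes,
increasingly so as `theta` and `P` grow.

### Numerics

* **Quadrature.** Gauss–Legendre nodes on the probability scale
  (truncated to `(1e-7, 1 - 1e-7)`; the truncated mass is reported as a
  diagnostic) are mapped through the noncentral-F and noncentral-t quantile
  functions: 64 outer x 96 inner nodes by default, doubling until two
  successive values agree to 1e-4 — the scale of four-decimal reporting —
  else an error with diagnostics. The doubled-grid value is returned.
* **Width function.** Bulk noncentrality inversions on quadrature grids and
  simulation replicates use the cdflib inverse (`scipy.special.nctdtrinc`);
  it agrees with the bracketed solver behind `exact_ci` to ~1e-6 in the
  noncentrality, far below the 1e-4 quadrature scale (asserted in the test
  suite). A monotone PCHIP interpolant of `d(|t|)` is available for
  Monte Carlo evaluation at scale.
* **Assurance event.** `d` is treated as unimodal with its minimum at 0,
  so `{d(T) <= c}` is `{|T| <= t*}` with `t*` the positive crossing found
  by bracketed root solving, and the inner probability is a CDF
  difference. Unimodality is not proven, so it is verified on a sampled
  grid before use (an error otherwise); a brute-force indicator
  integration with 2,000 midpoint nodes per outer node cross-checks the
  event calculation in the test suite at the 1e-3 grid-resolution scale.
* **Small nu.** At `nu = 2..3` the inner integrand's algebraic tail makes
  the 1e-4 doubling check unreachable for the expected width;
  `expected_width_exact` then raises rather than returning an unconverged
  value. Such residual degrees of freedom only arise for total sizes
  within a few subjects of `G + P`, far below any size a precision
  criterion selects in practice. The assurance quadrature, whose integrand
  is bounded, converges there.

## Sample-size search

`min_NT_expected_width` and `min_NT_assurance` walk the ratio lattice
`N_i = r_i n`, `n = 1, 2, ...` (starting at the smallest n with every
`N_i >= 2` and `nu >= 2`) by linear ascent — monotonicity of the assurance
criterion in N is an empirical observation, not a theorem, so no bisection
is attempted and every plan carries a certificate: the criterion holds at
the returned size and fails at the preceding lattice size. Sizes whose
width floor `a^{1/2} d(0)` already exceeds `omega` are declared infeasible
without quadrature (`W >= a^{1/2} d(0)` pointwise), which both speeds the
scan and keeps it away from the small-nu regime above. Non-integer ratio
vectors are rejected rather than rounded, since rounding would silently
change `a`. Ties at the criterion boundary count as feasible. The search
caps at `N_T = 20,000`.

## Monte Carlo engines

* **Conditional coverage** (`simulate_coverage`): holds the design and
  covariate statistic fixed — `psi_hat ~ N(psi, sigma^2 V)` and
  `sigma_hat^2 = sigma^2 chi^2(nu)/nu` independently — and scores one- and
  two-sided coverage of all three intervals. Defaults reproduce the
  worked example's conditions (`sigma^2 = 3.2728`, `Q = 0.2131`, balanced
  G = 3, contrast {-1, 1/2, 1/2}). Exact-interval coverage is scored by
  the probability-integral pivot (the true value is inside the interval
  exactly when the noncentral-t CDF at `T_O`, evaluated at the true
  noncentrality, lies strictly between the tail levels), which is
  algebraically identical to forming both limits.
* **Full-model precision** (`simulate_precision`): draws covariates from
  the design's law, responses from the ANCOVA model (slopes all 0.5 by
  default — they are nuisance parameters; intercepts
  `psi sigma c / sum c^2`, which fixes the contrast at `psi` and is the
  only feature of the intercepts the width distribution depends on),
  refits every replicate, and records the exact interval's width. Singular
  fits are redrawn and counted; more than 0.1% is an error.
* **Reproducibility**: every engine is deterministic under its seed, with
  independent substreams for covariates and errors.
* **Non-normal variants**: errors may follow a t(10) law and covariates
  Exponential(1), Gamma(5, 5^{-1/2}), Laplace(0,1), Lognormal(0, 1/4), or
  Uniform(0,1); each is affinely standardized to zero mean and unit
  variance before the group means and covariance are applied, so `theta`
  is preserved across laws. (The gamma scale-versus-rate reading is
  immaterial after standardization.) The generator emulates the planning
  model exactly; what it does not emulate are features of real data such
  as heteroscedastic errors, group-specific slopes, measurement error in
  covariates, or missingness — passing tests therefore validate the
  computations under the stated model, not robustness to violations
  beyond the non-normal laws listed.

## Default problem sizes in the test suite

Deterministic checks run at the reference designs themselves. Monte Carlo
checks use 2,000 replicates for coverage and width validation (tolerances
widened to the corresponding binomial/3-standard-error scale) and 100,000
draws for the quadrature-versus-simulation oracle; the acceptance script
uses 10,000 replicates for its single simulated quantity.

## Known limitations

* Expected-width quadrature is unavailable at `nu <= 3` (see above).
* Reference agreement for the approximate (covariate-omitting) assurance
  probabilities is limited by the reference tabulation itself: an
  independent 4-million-draw Monte Carlo agrees with this package's
  crossing-point values to ~1.5e-4 while the published column differs by
  up to 7e-3 with erratic sign, so those table entries are reproduced only
  to that accuracy.
* Only single contrasts are covered — no simultaneous bands, multiplicity
  adjustments, omnibus tests, heteroscedastic or random-slope extensions,
  and no cost-constrained allocation or power-based planning.
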