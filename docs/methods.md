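# Methods

## Model

A recursive path model over p observed variables is an acyclic system of
linear structural equations with mutually independent normal residuals.
The package uses the "all-y" representation: every variable has an
equation, exogenous variables simply have no predictors, so their mean
and variance enter the parameter vector as an "intercept" and a
"residual variance".  This gives one code path for the implied moments
over all p variables,

  μ(θ) = (I − B)⁻¹ α,    Σ(θ) = (I − B)⁻¹ Ψ (I − B)⁻ᵀ,

with B the (strictly lower-triangular, up to permutation) coefficient
matrix, α the intercepts and Ψ = diag(ψ) — which is exactly what the
null-model bootstrap transforms need.  (I − B) is provably nonsingular
for any acyclic model, so this is asserted rather than guarded.

The reference model is the sequential two-mediator chain
X → M1 → M2 → Y with the indirect effect ι = β₁β₂β₃.  The package's
default form is the pure chain (M1 ~ X, M2 ~ M1, Y ~ M2); the general
form with free direct paths X→M2, M1→Y, X→Y and an optional covariate C
in every equation is available via
`sequential_two_mediator(direct_paths=True, covariate=True)`.  The chain
is the default because it is the hypothesized mediation structure, and
because the branch noncentralities — hence the power of every test —
depend on which nuisance paths are freed: freeing the direct paths
replaces each predictor's variance by its partial variance and visibly
lowers power at small N.

## Estimation

Under normality the joint log-likelihood factorizes over equations, so
the **full-model MLE** is exact per-equation least squares with
divisor-n residual variances; no iterative optimization is involved.
All estimation runs on the sufficient statistics (n, ȳ, divisor-n S),
making a fit O(p³) regardless of the number of rows.

The **null model** maximizes the same likelihood subject to
g(β) = β₁β₂⋯β_k = c:

* **c = 0.** The constraint set is the union of the hyperplanes
  {β_j = 0}; on each, the constrained MLE is again closed-form least
  squares with that coefficient removed.  The solver enumerates the k
  branches and keeps the best — the exact global optimum, with no
  convergence failures.  A generic multi-start SLSQP over the full
  parameter vector (variances on the log scale for positivity; start 1
  zeroes the smallest-magnitude constrained coefficient of the full
  MLE, further starts jittered, K = 5) is retained as
  `fit_null(..., solver="slsqp")` and is cross-checked against the
  branch solver in the test suite.
* **c ≠ 0** (profile-likelihood endpoints).  Given values of the
  constrained coefficients, every other parameter has a closed-form
  optimum, so the problem reduces to the k constrained coefficients.
  When these sit in distinct equations — always true for a mediation
  chain — the profiled objective separates: −ℓ(t) = const +
  (n/2) Σ_j log ψ_j(t_j) with ψ_j an exact quadratic in t_j (recovered
  from three evaluations).  The reduced problem is solved by damped
  Newton on the KKT system (analytic Jacobian, backtracking on the
  residual norm) from a deterministic family of starts: the rescaled
  full MLE, the k single-coordinate continuations, an equal-magnitude
  point, and all sign patterns compatible with the constant — the
  constraint surface has several sign components and the global optimum
  can switch components as c crosses small values.  SLSQP is the
  fallback for starts where Newton stalls.  Newton refinement to
  ‖KKT‖ < 1e-11 matters: optimizer jitter of ~1e-4 in the LRT would
  defeat the endpoint root-finding below.

Nesting (LL_full ⩾ LL_null − 1e-6) is asserted after every constrained
fit; the constraint must hold to |g(β̂) − c| ⩽ 1e-8; residual variances
below 1e-10 trigger a boundary warning, consistent with the regularity
requirement that the null optimum not lie on the variance boundary.

Degrees of freedom are the number of independent equality constraints
(1 for the product), not a parameter-count heuristic.

## The three MBCO tests

All three share T = −2(ℓ_null − ℓ_full), clipped to 0 (values in
(−1e-6, 0) are roundoff; anything lower raises an internal-consistency
error).  Rejection is for *large* T.

* **Asymptotic:** p = P(χ²(1) > T).
* **Parametric bootstrap:** draw N rows from N(μ̂⁰, Σ̂⁰), refit both
  models, repeat R times; p = #{T* > T}/R.  The plain proportion is
  used (ties have probability zero for continuous data); the
  (b+1)/(R+1) correction is available as `corrected=True`.
* **Semi-parametric bootstrap:** with S = U_Sᵀ U_S and
  Σ̂⁰ = U₀ᵀ U₀ (upper-triangular Cholesky factors), each centered row is
  mapped by U₀ᵀ U_S⁻ᵀ and the null-implied means are added back, so that
  cov(y*) = Σ̂⁰ — an identity the code verifies at run time to 1e-10.
  Mean handling is a documented choice: the algebra equates covariances
  only, so rows are centered at the sample means before the linear map
  and recentered at μ̂⁰, making the resampling distribution match the
  null model in both moments.
* Bootstrap replications whose refits fail (degenerate resample) are
  dropped and counted, never imputed; the p-value denominator is the
  number of successes, and a failure rate above 10% flags the result.

At the parameter point where *all* constrained coefficients are zero,
the constraint gradient vanishes and T is the minimum of the k branch
statistics; the test is then strongly conservative (rejection
≈ 0.05^k), a singularity of the product constraint rather than an
implementation artifact.  On the regular part of the composite null
(exactly one coefficient zero) T is χ²(1) and the empirical size falls
inside Bradley's interval — both regimes are covered by tests.

## CI-based comparison tests

Each method builds a 100(1−α)% interval for ι; its test rejects iff 0
is outside.  Empirical quantiles are type-7 (linear interpolation)
throughout.

* **Percentile bootstrap:** resample rows, refit the full model, take
  the α/2 and 1−α/2 quantiles of the R products (default R = 1000).
* **Monte Carlo:** draw (default 100,000) coefficient vectors from
  N(MLEs, asymptotic covariance), multiply, take the same quantiles.
  The coefficient covariance comes from the observed information of the
  joint likelihood, which is block-diagonal across equations
  (ψ̂_v (ZᵀZ)⁻¹ per equation; coefficients from different equations are
  asymptotically uncorrelated) — verified against statsmodels in tests.
* **Profile likelihood:** endpoints are the extreme values of c where
  −2[ℓ_prof(c) − ℓ_full] equals χ²_α(1) (3.841 at 95%), located by
  doubling-step bracket expansion from ι̂ outward (failure beyond
  10·|ι̂|+1 raises, a decreasing trace warns of non-unimodality) and
  Brent root-finding; the equality holds to 1e-4 at returned endpoints.
  By construction this test's decision coincides with the asymptotic
  LRT's.

## Synthetic data

The generator reproduces the study conditions: standardized scale
(residual variances chosen so every variable has implied variance 1,
which requires β small enough that 1 − structural variance > 0), X
standard normal, chain coefficients β₁ = β₂ = β₃ ∈ {0, 0.14, 0.36,
0.48}, all other paths zero unless overridden, N ∈ {50, 100, 200, 500}.

Non-normality targets marginal skewness/kurtosis pairs (2, 7) and
(3, 21), interpreted as **excess** kurtosis: the Fleishman third-order
polynomial a + bZ + cZ² + dZ³ (a = −c) has no real solution for the
"raw 7" reading (excess 4) at skewness 2, while both pairs solve
cleanly as excess — and the excess convention is what standard SEM
simulation code uses.  The cubic moment equations are solved by a
quasi-Newton root finder to 1e-10; among multiple real roots the one
with b > 0 and minimal c² + d² (least distortion, matching the
published coefficient tables) is chosen deterministically.

Two placements of the non-normality are supported:

* `nonnormal_mode="observed"` (default): the observed vector is drawn
  jointly by the Vale–Maurelli construction — correlated normals whose
  *intermediate* correlations solve the cubic
  r = ρ(b² + 6bd + 9d²) + 2c²ρ² + 6d²ρ³, then univariate Fleishman
  transforms — so the sample matches the model-implied covariance in
  population *and* every marginal hits the moment targets.  This is how
  the field's standard simulation tooling realizes marginal
  non-normality, and it preserves the distinctive behavior of the
  percentile bootstrap under heavy tails.
* `nonnormal_mode="residual"`: independent Fleishman transforms of X
  and the structural shocks (no intermediate-correlation matching is
  needed since shocks are independent).  Residual-level non-normality
  degrades all tests' small-sample power more than the observed-level
  construction does.

What passing tests on these data do **not** show: behavior under
dependence structures other than the recursive normal-copula-like
construction above (e.g. heteroskedastic residuals, nonlinear
mediation, measurement error), under missing data, or with binary X —
all outside the generator's scope.

## Simulation harness

A design cell (method, β, N, distribution) runs n_reps replications at
α = 0.05; every source of randomness derives from one `SeedSequence`
spawn per replication, so cells are reproducible bit-exactly and safe
under joblib parallelism.  Failed replications are dropped, counted,
and invalidate the cell beyond 5%.  Type I cells are classified against
Bradley's liberal interval [0.025, 0.075] (accurate / liberal /
conservative).  Defaults follow the reference design (1000 reps, 1000
bootstrap draws, 100,000 Monte Carlo draws); the acceptance script runs
bootstrap-method cells at a reduced scale (300 reps × 199 draws), the
package's documented desk scale, with correspondingly wider tolerances
in the tests (0.06 absolute versus three Monte Carlo standard errors at
full scale).

## Known limitations

* Only equality constraints are implemented; one-sided hypotheses
  g(β) ⩾ 0 are representable in the constraint syntax but not tested.
* Latent variables, correlated residuals, non-recursive systems,
  ordinal/categorical indicators, multilevel structure and missing data
  are out of scope.
* The asymptotic test's conservatism at the all-zero singular point is
  inherent to the product constraint; the bootstrap variants inherit it
  because they bootstrap the same statistic.
* Robust (sandwich) standard errors are not provided; the Monte Carlo
  CI's coefficient covariance assumes the normal working likelihood.
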