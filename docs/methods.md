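# Methods

This note records the statistical model the package implements, the numerical
choices behind the implementation, and its limitations.

## Model

### Margins: zero-inflated generalized Poisson

Each count margin `Y_l` (l = 1, 2) follows a zero-inflated generalized
Poisson (ZIGP) law. The generalized Poisson (GP) component in the Consul
parameterization has

```
theta_l = mu_l / (1 + phi_l * mu_l),      lambda_l = phi_l * mu_l / (1 + phi_l * mu_l),
P(Y = y) = theta (theta + theta*phi*y)^(y-1) exp(-theta(1+phi*y)) / y!
```

with mean `mu_l` and dispersion `phi_l >= 0`; `phi_l = 0` recovers the
Poisson distribution exactly. Underdispersion (`phi < 0`) is out of scope:
it truncates the support and breaks the normalization identities the rest of
the package relies on. Zero inflation mixes a point mass at zero with
probability `p_l` into the GP component.

### Joint law: multiplicative correlation factor

The two margins are coupled through a multiplicative factor in the style of
Lakshminarayana, Pandit and Rao: the joint pmf multiplies the product of the
count components by

```
1 + eta * (exp(-y1) - g1) * (exp(-y2) - g2),      g_l = E[exp(-Y_l)].
```

For the GP component, `g_l = exp(theta_l (s_l - 1))` where `s_l` solves the
implicit equation `ln s = lambda (s - 1) - 1`. The joint pmf splits into
four cases by zero pattern — (0,0), (0,+), (+,0), (+,+) — because the
structural-zero mass enters the zero cells additively while the factor
applies only to the count components. With admissible `eta` the pmf is
non-negative and sums to one exactly; the package verifies the normalization
on the truncated support grid.

`eta` is admissible on an interval determined by the extreme values of
`exp(-y) - g_l` over the support. The implemented bound (factor
non-negativity at the extreme products) is slightly conservative: the joint
pmf can remain non-negative somewhat beyond it because structural-zero mass
pads the zero cells. Evaluation routines additionally detect an actually
negative pmf and raise.

### Regression structure

At each location `s_i = (u_i, v_i)`:

```
log mu_l(s_i)      = x_i' beta_l(s_i)        (Poisson state)
logit p_l(s_i)     = x_i' gamma_l(s_i)       (zero state)
```

The global model (BZIGPR) holds `gamma_l, beta_l, phi_l, eta` constant over
space. The geographically weighted model (GWBZIGPR) refits the full
parameter vector at every location by maximizing the kernel-weighted
log-likelihood `sum_j w_ij * ln f(y_1j, y_2j | theta(s_i), x_j)`.

## Estimation

### BHHH with a quasi-Newton polish

Each fit maximizes the (weighted) log-likelihood over a free-scale
parameter vector: regression blocks unchanged, `log phi_l` (clipped at ±50),
and `eta` through a scaled logit over a frozen admissibility interval. The
interval is derived from the data at the starting value, padded by a factor
0.999 so the transform never sits exactly on the boundary, and is shared
between a global fit and the local fits warm-started from it. Re-deriving
the interval at a different parameter value can genuinely move a
boundary-pinned `eta`; this is why the interval is frozen per analysis.

The optimizer is BHHH: per-observation scores `g_i` are central finite
differences of the weighted log-density (step `1e-5 * max(1, |x_j|)`,
forward difference at a lower bound, automatic step shrinkage on non-finite
values), the ascent direction is `(sum g_i g_i')^{-1} sum g_i` with ridge
escalation on singularity, and step halving enforces a non-decreasing
objective. Analytic derivatives are not used: the published derivations of
the score equations are not available in full, and finite differences of
the exact log-density are accurate to ~1e-6 relative error, which the score
validation tests check directly.

The outer-product update converges only linearly near the optimum, so once
the per-iteration improvement falls below `1e-8 * (1 + |loglik|)` the
iterate is handed to a BFGS polish on the summed objective, with gradients
assembled from one batched central-difference evaluation. Sub-noise BHHH
steps are never committed; a fit started at an optimum therefore returns
its starting point exactly, which is what makes the unit-weight
geographically weighted fit collapse to the global fit at tolerance 1e-6.

Standard errors come from the inverse outer-product-of-gradients matrix,
transformed to the natural scale by the delta method. When `eta` saturates
its admissibility bound its score column vanishes; the OPG matrix is then
inverted by a scaled pseudo-inverse and the degenerate coordinate's SE is
reported as NaN rather than a misleading finite number.

Initialization: each margin is fitted as a univariate ZIGP (started from a
Poisson GLM and a moment-matched zero excess), and `eta` starts at zero.

### Kernels and bandwidth

Four kernel families: fixed and adaptive versions of the Gaussian
(`exp(-(d/h)^2 / 2)`) and bisquare (`(1-(d/h)^2)^2` for `d <= h`, else 0)
kernels. Adaptive bandwidths use the k-th nearest-neighbour distance,
inflated by 1e-9 so the k-th neighbour keeps positive bisquare weight.

Bandwidths are chosen by generalized cross-validation of the locally
weighted *linear* smoother, `GCV = n * RSS / (n - v1)^2` with `v1` the
smoother trace, summed over both responses — a fast proxy for the full
model. Fixed bandwidths are searched by golden section over the observed
distance range; adaptive neighbour counts by exhaustive scan over
`k in [q+2, n-1]`. Kernel families are then ranked by the AICc of the
fitted geographically weighted model, not by GCV.

## Inference

* Variance test: `VT = sum (y - ybar)^2 / ybar` against 1. The threshold is
  taken verbatim from the testing tradition this implements even though VT
  scales with n; the scale-free ratio `VT/(n-1)` is reported alongside.
* Correlation: `t = r sqrt(n-2) / sqrt(1-r^2)` with `n-2` df.
* Glejser heterogeneity test on squared raw residuals
  `y - (1-p)*mu`, two-equation multivariate regression,
  `G = -[n - q - 1 - (j - q + 1)/2] ln(|S_full|/|S_0|)` with `j = 2q`
  slopes and df `2q` by default (both configurable — the source notation is
  internally inconsistent).
* Likelihood-ratio tests `G² = 2(lnL_full - lnL_restricted)` for the joint,
  zero-state and Poisson-state slope blocks. Restricted models are refit
  with the tested slopes frozen at zero (intercepts, dispersions, `eta`
  free). Default df = number of zeroed slopes (times n for a
  geographically weighted fit).
* Partial Wald `Z = estimate / SE` with normal two-sided p-values;
  `exp(beta)` reported as Poisson-state rate multipliers and `exp(gamma)`
  as zero-state odds multipliers.
* `AICc = -2 lnL + 2r + 2r(r+1)/(n-r-1)`.
* Model-similarity F: per-degree-of-freedom deviance ratio between the
  global and geographically weighted models, with exact F quantiles.
* p-values are reported raw; no multiple-testing correction is applied.

## Synthetic data generator

The generator draws locations on a grid or uniformly in the unit square,
standard-normal predictors (optionally equicorrelated), builds coefficient
surfaces per block (constant, linear in coordinates, or a two-cluster
step), links them to `mu` and `p`, and samples pairs by inverse-CDF on the
truncated joint grid. Identical design + seed gives identical data. The
default surfaces use moderate effects with one exactly-zero coefficient per
block so both power and size properties of the tests are exercisable. A
companion fixture mimics the shape of a small-count two-response spatial
study — 91 locations, 7 standardized predictors, sub-unit means,
overdispersion, more than half zeros per margin — without reproducing any
real data.

## Numerical choices

* All pmf evaluation in log space; truncated supports end where GP survival
  mass drops below 1e-12 (hard ceiling 500). Near the dispersion limit the
  tail can exceed the ceiling, in which case the truncation misses up to
  ~1e-8 mass; the normalization tests restrict to interior caps.
* Linear predictors are clipped at ±30 before exponentiation (a guard
  against overflow during finite-difference probing; logged at debug
  level).
* The implicit equation for `s` is solved by fixed-point iteration (a
  contraction for `lambda in [0,1)`) with a Brent-bisection fallback, to
  residual 1e-10 or better.
* Convergence: free-scale step sup-norm <= 1e-6, maximum 200 BHHH
  iterations, 20 step halvings, BFGS polish gtol 1e-5.

## Limitations

* Underdispersed margins (`phi < 0`) are not supported.
* Scores and Hessians are finite-difference based; extremely flat or
  boundary-pinned likelihoods yield NaN standard errors by design rather
  than silently unstable ones.
* The GCV bandwidth is a linear-smoother proxy; for very small effective
  samples (narrow bisquare kernels) a local fit can have fewer positively
  weighted observations than parameters, which raises an estimation error
  naming the location instead of producing an unidentified fit.
* AICc for the geographically weighted model counts the per-location
  parameter dimension, not an effective number of parameters; comparisons
  should be read with that convention in mind.
* No spatial autocorrelation statistics (e.g. Moran's I) and no bootstrap
  inference.
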