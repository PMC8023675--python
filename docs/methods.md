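# Methods

## Sampling model and parameterization

Counts are modeled as Gamma-Poisson: a Poisson draw whose rate is itself
Gamma-distributed with mean `mu` and shape `1/theta`, giving

    E[y] = mu,    Var[y] = mu + theta * mu^2,    theta >= 0.

`theta` is the reciprocal of the classical negative-binomial "size"; this
parameterization is used because `theta = 0` then *is* the Poisson
distribution, which the code evaluates on a dedicated branch rather than
as a numerical limit. Overdispersions below `1e-16` are routed to the
Poisson branch as well: the pmf difference is below float precision
there, while `1/theta` in the gamma-function terms would lose all
accuracy.

The deviance is `2*[l(y; mu=y) - l(y; mu)]`. For `y = 0` the saturated
mean limit is taken analytically (`2*mu` for Poisson,
`(2/theta)*log1p(theta*mu)` otherwise) so the `0*log 0` terms vanish
exactly rather than through an epsilon.

## Coefficient estimation (IRLS)

Per gene, `log mu = X beta + log s` is fitted at fixed `theta` by Fisher
scoring: working weights `w = mu/(1 + theta*mu)`, working response
`z = eta + (y - mu)/mu`, each step solving the weighted least-squares
problem by an orthogonal decomposition (LAPACK `gelsd`), which is exact
for full-rank designs and deterministic. Steps that would increase the
deviance are halved, up to 20 times. Numerical choices:

- start: ordinary least squares of `log((y + 0.5)/s)` on `X`;
- convergence: relative deviance change `< 1e-8` or 100 iterations; the
  `converged` flag additionally requires the score to vanish to
  `1e-6 * (1 + |sum y|)`;
- the linear predictor is clamped to `[-30, 30]` against overflow; a fit
  ending on the clamp is flagged, as is `max|beta| > 50` (separation);
- all-zero genes short-circuit to the boundary fit (`log mu = -30`),
  flagged `all_zero`, rather than iterating.

Size factors enter only as offsets; counts are never divided, so the
integer structure the bundling exploits is preserved. The default
size-factor estimate is the column sum re-centered to geometric mean 1
("normed-sum"), which is defined for any cell with at least one count;
median-of-ratios is available for bulk or pseudobulk matrices where most
genes are positive in all samples, and falls back to normed-sum (with a
warning) when no gene is all-positive. User-supplied factors pass
through unchanged after a positivity check.

## Overdispersion estimation

`theta` is estimated by maximizing the profile log-likelihood at the
current fitted means, over `log theta` in `[log 1e-8, log 1e6]`, from a
method-of-moments start `max(0, sum((y-mu)^2 - mu)/sum(mu^2))` with
bracket expansion followed by bounded Brent refinement. The attained
objective is never allowed below the objective at the start; solutions
near the lower boundary (or beaten by the exact Poisson endpoint) are
returned as exactly 0. The Cox-Reid adjustment
`-1/2 log det(X' W X)` is applied by default to correct the downward
bias from estimating the `p` mean coefficients; it can be switched off.

The likelihood is evaluated through the bundled representation: unique
`(count, mean)` pairs with multiplicities, where means are merged only
within `1e-10` relative tolerance — i.e. only mathematically identical
means, as produced by group-like designs, ever merge, so the bundled and
dense evaluations agree to full precision by construction. When fewer
than half the observations collapse, the dense representation is kept so
the worst case costs no more than the naive evaluation.

The joint fit alternates IRLS (theta fixed) and the profile search
(means fixed) until `|delta log(theta + 1e-8)| < 1e-4` with a converged
beta, at most 10 rounds. Whether to alternate or to profile theta inside
a single outer optimization was an open design choice; alternation was
chosen because each half-step is monotone in its own objective and the
cross-dependence is weak (means move little as theta changes).

The dispersion-mean trend is a running median of the gene-wise estimates
over genes ordered by log mean expression (window `max(11, 5%)` of
genes), linearly interpolated in log-mean space and floored at `1e-8`.
A median was preferred over a parametric curve because gene-wise
estimates at small n are heavy-tailed and frequently hit the zero
boundary. With fewer than 10 usable genes the trend is the constant
median, with a warning.

## Quasi-likelihood test with shrinkage

Full and reduced models are both refitted at the *trended* theta (not
the gene-wise estimate), so the per-gene quasi-dispersion
`sigma^2 = deviance/df_residual` absorbs residual gene-level
variability; fitting at gene-wise theta instead is available as an
option. The prior is estimated by matching the first two moments of
`log sigma^2` to those of log of a scaled F variable: the prior df is
solved from the excess of the empirical variance over the
`trigamma(df/2)` chi-square contribution by Newton inversion of the
trigamma function. When the empirical variance is at or below the
theoretical minimum there is no detectable gene-to-gene spread and the
prior is infinitely concentrated at the geometric mean of the observed
values. The squeezed quasi-dispersion is the df-weighted average of the
gene value and the prior location; the F statistic

    F = [(dev_reduced - dev_full)/df1] / sigma^2_shrunk

is referred to `F(df1, df_prior + df_residual)`, with the chi-square/df1
limit when the prior df is infinite. The prior location is global by
default (a mean-dependent squeeze was considered out of scope). Deviance
differences in `[-1e-8, 0)` are clipped to 0 as floating-point guard;
anything more negative raises, since it indicates inconsistent fits. A
reduced design identical to the full one yields the degenerate test
`F = 0, p = 1` for every gene.

Multiple testing uses Benjamini-Hochberg step-up with stable ties;
missing p-values propagate without counting toward the number of tests.

## Pseudobulk

Counts are summed exactly (integer arithmetic) within sample labels;
every design covariate must be constant within a label. Size factors are
re-estimated on the aggregated matrix rather than combined from
cell-level factors, since the aggregated library sizes are what the
pseudobulk model sees.

## Chunked and on-disk execution

Genes are independent given the design and size factors, so fitting
streams over contiguous gene blocks; size factors come from a first
streaming pass over column sums. The on-disk backend reads 10x-style
HDF5 (CSC with genes as the first shape dimension), materializing one
gene block at a time with a bounded cell-column read buffer. MatrixMarket
and TSV inputs are parsed in memory (they are small-input formats here);
`write_10x_h5` converts them for on-disk use. Results are invariant to
backend and chunk size — this is asserted, not assumed.

## Synthetic data generator

The generator draws counts hierarchically (Gamma rate with mean
`mu = s * exp(X beta)` and shape `1/theta`, then Poisson; `theta = 0`
draws Poisson directly), so simulated data follow exactly the model the
estimators assume. One global integer seed determines everything;
per-gene streams are derived by counter-based seed-spawning so adding or
reordering genes never changes other genes' draws. Size factors are
log-normal with geometric mean 1.

Default study conditions used by the tests and the acceptance script,
chosen once as representative of a small replicated single-cell
comparison: two balanced groups, baseline means log-uniform on [5, 50],
size-factor log-sd 0.3 (passed as known factors so the checks isolate
the estimator, not the normalization), overdispersion 0.3-0.4. The null
calibration uses 2000 genes × 100 cells; parameter recovery uses 300
genes × 500 cells over theta in {0.1, 0.5, 1}; the power curve uses 20
cells per simulation so it is not saturated at the larger fold changes.

The generator emulates sampling noise, sequencing-depth variation and
design-driven mean structure only. It does not produce doublets, ambient
RNA, batch effects beyond design covariates, zero inflation, or
gene-gene correlation — so passing tests demonstrate correctness of the
inference under the Gamma-Poisson model, not robustness to artifacts
real data may carry.

## Known limitations

- The trend is a running median; very sharp dispersion-mean
  relationships are smoothed over the window.
- No shrinkage of log fold changes, no ridge priors on `beta`, no
  mixed models or cell-level weights.
- Gene-wise dispersion estimates at very small n sit on the zero
  boundary often; downstream testing is deliberately based on the
  trended value plus quasi-dispersion, which is robust to this.
- The QL test's type-I error is calibrated under the generative model;
  with strong unmodeled structure (batch, doublets) the usual caveats
  for GLM-based DE apply.
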