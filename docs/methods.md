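# Methods

## The problem

Per-base read counts from ChIP-seq, DNase-seq and RNA-seq are almost always
overdispersed: the variance of counts across bases exceeds the mean, often
severalfold, while most downstream tools (peak callers, footprint callers,
windowed significance tests) assume Poisson counts either explicitly or
through their test statistics.  `fixcount` corrects the data rather than the
tools: it fits a flexible compound-Poisson model to the per-base count
histogram and then maps every count through a quantile (probability-integral)
transform onto a Poisson reference, so that a Poisson-assuming tool sees
calibrated counts with the original rank order and joint positional
structure intact.

## Model

Each base `i` carries a latent log-rate `lambda_i` drawn i.i.d. from a
distribution with *log-concave* density `f = exp(g)`, `g` concave; the
observed count is `n_i ~ Poisson(exp(lambda_i))`.  Log-concavity is the key
modelling choice: it is a nonparametric family (no shape parameters to pick)
that contains the latents of all the classical overdispersion models --
a point mass (pure Poisson), gamma rates of any shape when expressed on the
log-rate axis (negative binomial marginals), and normal log-rates
(log-normal-Poisson) -- yet excludes pathologically multimodal or
super-heavy-tailed latents, which keeps the MLE well behaved.

The latent density is represented by its values `g_j` on a uniform grid of
`K` quadrature points spanning `[log(0.5/N), log(max count) + 3]`: from rates
at which less than half a read is expected in the whole dataset to well above
the largest observed count.  The marginal log-likelihood of the count
histogram `{c_k}` (with `N = sum c_k` bases) is

    L(g) = sum_k c_k log( sum_j Pois(k | e^{x_j}) e^{g_j} )  -  N log( sum_j e^{g_j} )

Rectangle quadrature weights cancel between the two terms, so `L` is
invariant under adding a constant to `g`; the fitted density is pinned at
`max_j g_j = 0`.  The likelihood is concave in the latent cell *masses*
`w_j ∝ e^{g_j}` (each term is the log of a linear function of `w`), which
is what makes the estimation problem well posed.  In the log-density
parameterisation `g` actually optimised over -- required to express the
concavity constraint linearly -- the objective is a difference of
log-sum-exp terms and need not be globally concave, so the optimiser's
solution quality is validated empirically: on simulations whose true latent
is itself log-concave (gamma, log-normal), the fitted likelihood must reach
or exceed the corresponding parametric MLE, and does in every test.

### Tunable parameters

| parameter | default | meaning / why |
| --- | --- | --- |
| `K` (quadrature points) | 4096 | grid resolution in log-rate; the objective depends on the grid only through quadrature error, and refining an analytic latent from K=4096 to K=32768 moves marginal probabilities by < 1e-6 (tested).  Configurable up to 1e6 via `--quadrature-points`. |
| grid span | `[log(0.5/N), log(kmax)+3]` | covers every rate the data can inform. |
| `max_iter` | 2000 | cap on proximal-gradient iterations; converged runs stop far earlier via the windowed rule. |
| `obj_tol`, `g_tol`, `window` | 1e-8, 1e-8, 50 | stopping: mean per-base objective gain per iteration over the trailing window below `obj_tol`, or sup-norm iterate movement over the window below `g_tol`.  A *windowed* rule is used because per-iteration gains on this objective can sit below any per-iteration threshold thousands of iterations before the iterate stops moving. |
| target rate `mu` | median of the fitted latent rate distribution | the transform's free parameter; any fixed choice yields an equivalent monotone re-weighting, and the median is scale-appropriate for the data.  Override with `--target-rate` to place several samples on a common scale. |
| rounding replicates | 30 | randomized-rounding replicate count at which downstream performance saturates. |

## Inference

The fit is accelerated proximal gradient ascent: a Nesterov momentum step on
the smooth concave objective followed by Euclidean projection onto concave
sequences (concave regression) as the proximal operator, with a backtracking
(Armijo) line search, adaptive restart, and the monotone variant that never
accepts an objective decrease.  Repeated runs are bit-identical.

Two implementation choices matter in practice:

**Initialisation.**  Any concave sequence is an affine part plus a
non-negative combination of negative hinge functions `-(j - m)_+`, so the
constrained MLE can equivalently be written as a *box-constrained* smooth
concave programme in the hinge coefficients.  The fit first runs L-BFGS-B in
this parameterisation (hinge columns normalised so the quasi-Newton model
sees balanced curvature, up to 4 restarts) and hands the result to the
proximal-gradient loop.  Starting essentially at the optimum means every
subsequent proximal step is only mildly infeasible and cheap to project;
without this the gradient steps early in the run produce projections whose
active sets are expensive to identify.

**Projection.**  `project_concave` solves the weighted least-squares
projection onto `{u : u_{j+1} - 2u_j + u_{j-1} <= 0}` exactly, via
complementary active-set strategies tried in order of expected cost: a
primal-dual active-set pass over the tight constraints (the Gram matrix of
selected second-difference rows is banded, bandwidth 2, so each pass is a
banded Cholesky solve); if that cycles, L-BFGS-B on the box-constrained dual
followed by another active-set pass; then Lawson-Hanson NNLS in the hinge
basis, whose working set is the (usually small) knot set of the
piecewise-linear solution; and as a last resort the least concave majorant
of the best iterate, which is always feasible.  The projector agrees with
scipy's NNLS on the dual cone programme to ~1e-8 and with SLSQP on the
primal to SLSQP's own accuracy, and its output is concave by construction on
the hinge path (second differences are negated non-negative coefficients).

The cost per fit iteration is `O(L*K)` with `L` the number of *distinct*
observed count levels, so fitting cost is independent of genome size: a
genome-scale dataset reduces to the same histogram computation.

## Count adjustment

With the fitted density, the compound model's continuous CDF at integer `k`,
`F(k) = sum_j w_j Q(k+1, e^{x_j})` (with `Q` the regularised upper incomplete
gamma function, i.e. the continuous extension of the Poisson CDF), equals the
exact discrete compound CDF.  The adjustment is

    t_k = F_cPois^{-1}( F(k); mu ),

the value at which a continuous Poisson with the target rate reaches the same
quantile.  The map is strictly increasing, so ranks are preserved -- a
rank-preserving transform can only re-weight counts, never fully collapse
them, which is exactly what separates this correction from de-duplication.
The probability integral transform is applied deterministically through the
CDF evaluated at the integer count (reproducible and rank-preserving); a
randomized-PIT variant would draw `u` uniformly between `F(k-1)` and `F(k)`
and is deliberately not the default.

Numerics: the inverse is a bracketed Brent root-find on `[0, mu + 20*sqrt(mu)
+ 20]` (bracket expanded on demand) with 1e-12 tolerance; quantiles near 1
invert the survival function instead of the CDF, switching to a log-survival
branch once the survival probability underflows toward 1e-14, so deep-tail
counts map to finite, increasing values.  Values of `u` below `F_cPois(0)`
would formally map to `t in (-1, 0)`; they are clamped at 0 (adjusted counts
are non-negative).  De-duplication emerges as the degenerate limit: under a
zero/uniform-noise count model every nonzero level is equally probable and
the fitted transform sends all of them into a band less than one adjusted
unit wide.

## Rounding

For tools that need integers: flooring (deterministic, a generalisation of
de-duplication -- on strongly overdispersed data it collapses a wide range of
raw counts onto a few small integers while preserving monotonicity) and
randomized rounding `floor(t) + Bernoulli(t - floor(t))`, which is unbiased
for `t`.  Randomized rounding produces replicate datasets; 30 replicates is
the default.  Each replicate uses a Philox stream keyed by `(seed,
replicate)` over records in canonical (chrom, pos) order, so draws do not
depend on traversal order and any single replicate can be regenerated alone.

## Baselines and diagnostics

Poisson, negative binomial (profile MLE in log-size; the mean's MLE is the
sample mean analytically), log-normal-Poisson (Gauss-Hermite quadrature with
61 nodes; Nelder-Mead from a moment-matched start plus seeded random
restarts), and the de-duplicated Poisson (Poisson fit after collapsing all
positive counts to 1, evaluated against the collapsed data).  The diagnostic
is the per-level log-likelihood error `e_k = log(c_k/N) - log P_model(k)`;
its count-weighted mean equals `KL(empirical || model)` and is the expected
per-base error of a log-likelihood-based test statistic.  Both the per-level
profile and the per-base mean are reported, covering both readings of a
"per-base log-likelihood error".

## What the simulations do and do not show

The generator draws i.i.d. per-base rates (degenerate, gamma, log-normal, or
an arbitrary gridded log-concave density via cell sampling with in-cell
uniform jitter) and Poisson counts, with a depth factor that scales all
rates, emulating deeper sequencing of the same library.  All these latents
are log-concave on the log-rate axis, so end-to-end recovery tests run under
a correctly specified model.  Real data differ in ways the simulation
deliberately omits: spatial dependence between neighbouring bases (the model
treats bases as independent, as do the downstream tools being calibrated),
mappability and GC structure (delegated to covariate-correction tools), and
latent distributions outside the log-concave family.  Passing tests
therefore demonstrate correct inference and calibration under the model's
own assumptions, not that any particular real assay satisfies them.

Three statistical caveats surfaced by the tests are worth recording.  First,
with Poisson-distributed input the fitted latent honestly absorbs the
*sample's* chance dispersion: a sample of 1e5 bases whose dispersion index
deviates from 1 by `delta` (sd ~0.0045) yields a transform deviating from
the identity by roughly `20*delta` at count 10, so near-identity holds only
as tightly as the sample is Poisson-dispersed.  Second, the mean per-base
error of the *correctly specified* log-concave fit against the empirical
histogram is a pure noise floor, `E[2N*KL] ~ (#occupied count levels -
effective dof)`; it necessarily grows with sequencing depth because deeper
data occupy more count levels.  Depth-stability of the log-concave error on
real data reflects model misfit dominating that floor at genome scale, not
the floor itself being flat.  Third, the correction is *approximately*
Poissonizing, not exactly: the deterministic quantile map places each raw
level's mass at a single adjusted atom, and randomized rounding
redistributes it to the two neighbouring integers with residual per-level
errors of a few percent.  The dispersion index of rounded adjusted counts
returns to ~1 (from 5 on the gamma benchmark), but a chi-square
goodness-of-fit test against Poisson will still reject at large n because
it has power against the approximation error itself -- this is true even
when the exact data-generating latent is used in place of the fit, so it is
a property of discrete-to-discrete quantile mapping, not of estimation
error.  (The randomized-PIT variant does not help: its extra rounding noise
inflates the dispersion index to ~1.2.)

## Problem sizes used

Simulated studies run at 1e5 bases.  Full-size fits use K = 4096; the
depth-factor sweep uses K = 1024 and the unit-test fixtures K = 512 with 3e4
bases -- the objective depends on K only through quadrature error, which is
orders of magnitude below every tolerance asserted at those sizes.

## Known limitations

* A single genome-wide latent distribution: no per-chromosome or locally
  varying rates, no mixtures of log-concave densities, no covariate
  corrections.
* The histogram is the sufficient statistic; any preprocessing that alters
  it (e.g. prior duplicate removal) is taken at face value.
* The transform matches marginal quantiles; it cannot restore information
  destroyed upstream, and fractional outputs require rounding (with its
  replicate-count trade-off) for integer-only downstream tools.
* EM over grid weights is not offered even as an oracle: unconstrained EM
  converges to the unconstrained nonparametric MLE, which is not the
  concavity-constrained optimum; the nesting checks against parametric MLEs
  play the cross-validation role instead.
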