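# Methods

## Setting and model

`swdsim` studies the analysis of stepped-wedge cluster randomized trials
(SWDs) whose outcome is an aggregate event count per cluster-period — the
motivating case is county-level opioid overdose deaths observed over
thirteen 3-month periods in 18 communities, with two communities crossing
over to the intervention at the start of each of nine rollout periods after
a two-period baseline, and a two-period all-intervention follow-up.

Counts are modeled as Poisson rates with a population offset,

    log E[Y_ij] = log O_i + eta_ij ,

and the intervention effect `theta` is a log rate ratio (the default
`theta = log 0.6` is a targeted 40% reduction in the death rate).  The ten
analysis models share the fixed-effect core `alpha + theta X_ij`, differ in
the main fixed time effect (discrete period dummies, reference-coded with
`beta_1 = 0`, or a linear trend `beta t_j` with `t_j` in months from study
start), optionally add a fixed control-group trend
`gamma t_j 1{X_ij = 0}`, and place one of seven random-effect covariance
structures on cluster-level time effects (random intercept; i.i.d.
cluster-period effects; an unstructured period-by-period covariance; a
correlated intercept + slope pair; and control-group-augmented "group by
time" versions of the latter three).  Control-group random effects exist
for a cluster's control periods `1 .. t^I_i - 1`; their covariance is the
leading principal submatrix of the full control-block covariance (the block
belonging to the latest-rolled cluster).

## What the data generator emulates

The generator reproduces three disturbance processes that plague real
stepped-wedge studies of epidemic interventions, each deliberately drawn
from a *different* family than the analysis models assume (uniform latent
effects, not Gaussian), so that simulation results speak to robustness
rather than to self-fulfilling correctness:

- **Confounding by calendar time** ("rising tide"): each not-yet-exposed
  cluster is exposed with probability `1/N` per period; exposure is
  absorbing; after onset the cluster's log rate is shifted by
  `beta_ij ~ unif[-1, 0]` (count-decreasing direction) or `unif[0, 1]`
  (count-increasing), redrawn independently every period.
- **Early intervention adoption** (noncompliance): each still-control,
  not-yet-adopting cluster adopts with probability `(N - N* + 1)/(2N)`
  where `N*` is the current at-risk pool, so the per-cluster hazard grows
  as the trial rolls out; an adopting cluster's control periods receive
  `theta_ij ~ unif[theta, 0]`, again redrawn each period, and the window
  closes at its scheduled rollout.
- **Time-varying effect modification** uses the same combined mechanism
  with `beta_ij` read as the external-factor effect in intervention
  communities and `theta_ij` as the control-vs-intervention difference.

Cluster random intercepts are `N(0, 0.30^2)` and the baseline log rate is
`alpha = -10`.  County populations are not packaged; the default offset
generator draws `O_i` log-uniformly on `[5e4, 5e5]` persons under a fixed
seed, giving baseline expectations of about 2.3–22.7 deaths per
cluster-period at `alpha = -10` — a realistic county scale.  Users may
supply their own offsets.  What the generator does **not** emulate:
spatially or socially correlated exposure, individual-level outcomes,
non-Poisson dispersion beyond what the latent processes induce, and
intervention effects that vary with time since rollout.  Passing tests
therefore certify behavior under *these* stylized disturbance processes,
not under every real-world departure.

### Randomness discipline

Every replicate derives a `numpy` `SeedSequence` keyed by
`(scenario, arm, replicate)` from the master seed, so results are
independent of execution order and parallelism, and all models in a cell
see the same datasets.  Inside a replicate, rollout randomization,
intercepts, confounding exposure, adoption, period effects and counts each
draw from their own child stream; switching a process off (or setting
`theta = 0`, which degenerates `unif[theta, 0]` to zero) leaves the other
streams untouched.  A useful consequence: the early-adoption scenario under
the null is *identical*, draw for draw, to the standard scenario — which is
why early adoption cannot inflate Type 1 error even though it biases the
effect estimate.

## Estimation

The fitter maximizes a Laplace-approximated marginal likelihood written
directly for this model family rather than delegating to an existing
mixed-model package.  Random effects are whitened (`u = L v` with `L` the
log-Cholesky factor of the covariance), so the per-cluster inner problem is
strictly concave with Hessian `L'Z'WZL + I` that stays well conditioned
even at variance boundaries; a damped Newton loop (step halving, modes
warm-started across outer iterations) locates the modes for all clusters in
batched linear algebra.  Clusters whose control block is lower-dimensional
are zero-padded to the maximal dimension: padded coordinates carry prior
mass but no likelihood, integrate out exactly, and realize precisely the
leading-submatrix covariance convention.

The outer problem — fixed effects plus unconstrained covariance parameters
(log-Cholesky: log SDs and free off-diagonal factor entries, making
positive semidefiniteness structural) — is solved by L-BFGS-B with an
*exact analytic gradient*, including the dependence of the modes and of the
log-determinant terms on all parameters (for the Poisson/log link
`dW/deta = W`, which closes the formulas without third-derivative
machinery).  The gradient is verified against finite differences in the
test suite.  This is what makes the unstructured structures practical: the
13-period unstructured covariance has 91 parameters, its group-by-time
extension 146.

Numerical choices:

- log-SD parameters are bounded to `[-8, 8]` (SDs from ~3e-4 to ~3e3);
  a solution at the lower bound is reported as a boundary fit
  (`"variance component at zero boundary"` warning), not an error.
- Fixed effects start at the Poisson GLM solution (an internal IRLS — the
  exact `sigma -> 0` limit of the objective).  Covariance parameters start
  at SD 0.1; the unstructured models 3/6/9 are warm-started from the fitted
  single-variance models 2/5/8 (initialization ladder).  Non-convergence
  triggers up to three restarts from jittered covariance starts; persistent
  failure is recorded in the result and excluded from study metrics with
  the exclusion fraction reported, never raised mid-batch.
- `SE(theta)` is the Wald standard error from the fixed-effect block of the
  observed information (negative Hessian of the Laplace objective in the
  fixed effects, covariance parameters held at their estimates), computed
  by central differences of the analytic gradient.  The metric tables
  report the *mean* of estimated SEs across replicates.
- Inner Newton tolerance scales with the cluster's total count; outer
  tolerances are `gtol = 1e-4` on the projected gradient and
  `ftol = 1e-11` relative on the objective.

An adaptive Gauss–Hermite quadrature implementation for scalar-random-
effect models ships as an independent validation oracle (it shares no code
with the Laplace path); the Laplace objective agrees with 21-node
quadrature to better than 1e-3 on the log scale on the test fixture, and
estimates agree with `lme4::glmer`-style fits to four decimals where both
converge.

## Study metrics

Per scenario × model cell, over converged replicates:
`%bias = 100 (mean theta_hat - theta)/theta` (negative = attenuation for a
protective effect; undefined under the null, where absolute bias should be
used), empirical SD of `theta_hat`, mean estimated SE, coverage of the
nominal 95% Wald CI at the true `theta`, power (rejection of `theta = 0` at
the 5% level under `theta = log 0.6` generation) and Type 1 error (the same
rejection rate under a parallel sweep generated with `theta = 0`
substituted everywhere, including the adoption-effect support, on a
disjoint seed substream).  At 500 replicates a proportion carries an MC SE
of at most `sqrt(0.25/500) ~ 0.022`; comparisons in the acceptance tests
use 3×MC-SE bands at the replicate counts actually run.

## Problem sizes

The shipped acceptance sweep (`scripts/acceptance.py`) runs models 1–4
under the three early-adoption scenarios at 300 replicates per cell (150
for the 91-parameter model 3), which reproduces the headline attenuation
range in a few minutes on one core.  The heavy group-by-time unstructured
cells (models 6 and 9) are exercised at 100 replicates with
correspondingly widened Monte Carlo bands — a deliberate scale-down; their
metrics stabilize at the same values at higher replicate counts.

## Design choices where the design was open

- **Model 2 as printed.**  The i.i.d. cluster-period structure is
  implemented exactly as specified — without an additional cluster random
  intercept.  A variant with an intercept (the form usually attributed to
  Hooper/Girling) pools information across a cluster's periods and yields
  visibly smaller between-replicate SD for models 2/5/8; the unstructured
  structures are unaffected because an unstructured covariance subsumes a
  cluster intercept (compound symmetry is a special case).  Bias metrics
  are insensitive to this choice.
- **Confounding direction labels.**  Scenario ids `2.1`/`4.1` denote the
  count-*decreasing* (beneficial, "rising tide") direction
  `beta_ij ~ unif[-1, 0]`, and `2.2`/`4.2` the count-increasing direction.
  Results tables always carry the scenario id, so the direction in force is
  unambiguous.  The two directions are not symmetric in their consequences:
  count-increasing confounding concentrates Poisson information in
  confounded cluster-periods and produces the stronger Type-1-error
  inflation (~0.22 vs ~0.12 for the random-intercept model).
- **Effect modification** is generated by the same mechanism as combined
  confounding + adoption rather than by a bespoke process; only the
  interpretation of the latent parameters changes.
- **Control-block dimension.**  The full control-block covariance is taken
  to span periods `1 .. max_i(t^I_i) - 1` (dimension 10 on the default
  design, 55 free parameters); each cluster uses its leading principal
  submatrix.  The realized free-parameter count is exposed in every
  `FitResult`.
- **Re-randomized rollout.**  Each replicate draws a fresh uniform
  assignment of clusters to rollout slots, reflecting a randomized SWD; a
  fixed-assignment mode (simply not calling `assign_rollout`) exists for
  debugging.

## Known limitations

- Laplace accuracy degrades for very small counts (few events per
  cluster-period); the default offset scale keeps counts in a range where
  the approximation error is far below Monte Carlo error (validated against
  quadrature).  For very sparse data, quadrature-based fitting would be
  preferable for scalar structures.
- The 91/146-parameter unstructured covariances are weakly identified from
  18 clusters; fits routinely end on variance boundaries, and different
  near-optimal covariance solutions can coexist.  The intervention-effect
  estimate is insensitive to this in our experiments, but variance
  component estimates from those models should not be over-interpreted.
- GEE estimators, randomization-based inference, exponential-decay
  covariance structures, non-Poisson outcome families, incomplete designs
  (cluster-specific period grids) and time-varying intervention effects are
  out of scope.
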