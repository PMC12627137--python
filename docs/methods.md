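# Methods

## The problem and the pipeline

Individual-differences research on attentional control asks whether
performance costs in conflict tasks (Stroop, flanker, Simon, ...) share a
common latent factor across tasks.  Two methodological objections to the
classic difference-score approach are (a) that RT difference scores
compound trial-level measurement noise, and (b) that pure-RT measures
ignore individual differences in speed–accuracy trade-offs.  This package
implements the two-stage inference designed to address both at once:

1. a **hierarchical Bayesian Wiener diffusion model** is fitted to
   trial-level choice/RT data across all tasks jointly, with the
   variance–covariance matrix of the subject-level parameters estimated as
   a model parameter rather than computed post hoc from point estimates;
2. **confirmatory factor analysis** (single-factor and bifactor) is applied
   to the posterior of that covariance matrix — once at the posterior mean,
   and repeatedly across covariance matrices sampled from the posterior,
   to propagate the uncertainty of the correlations into SEM fit and
   reliability statements.

## Measurement model

Each trial contributes a two-boundary Wiener first-passage-time density
with drift `v`, boundary separation `a`, non-decision time `t0` and start
fraction `w = 1/2` (accuracy coding: upper boundary = correct).  The
diffusion coefficient is fixed at 1, which sets the scale of `v` and `a`.
Across-trial variability parameters and contaminant mixtures are
deliberately absent: the model is the simplest variant that accounts for
the joint RT/accuracy distribution, trading a little bias for much lower
estimator variance.

The density is evaluated with the standard dual series (small-time and
large-time expansions of the same function); per evaluation point the
series needing fewer terms at target precision `1e-7` is used.  Analytic
gradients with respect to `(v, a, t0)` are implemented alongside the
density (and checked against finite differences in the test suite); a
numba-compiled kernel accelerates the trial loop when numba is available,
with the pure-numpy implementation kept as the reference path.

Trial simulation draws the choice from the closed-form absorption
probability `P(correct) = 1/(1 + exp(-v a))` and the decision time by
numerically inverting the conditional first-passage-time CDF on a dense
log-spaced grid; the Kolmogorov–Smirnov distance between simulated RTs and
the density is below 0.01 at n = 1e5 (asserted in the suite).

## Hierarchical structure and priors

Fixed effects: per task, one boundary and one non-decision parameter; for
the drift either a baseline mean plus a congruency-difference parameter
(**difference coding**, congruent/incongruent trials only; a positive
difference means lower drift under high control) or one mean per trial
type (**condition coding**).  The high-control condition defaults to
incongruent; negative-compatibility-style tasks invert this via the
control-role map.  Every fixed effect carries a by-subject random effect;
on the unconstrained real line (no link functions)

    theta_s = beta + u_s,   u_s ~ MVN(0, diag(tau) Omega diag(tau)).

Priors: LKJ(eta = 1) on `Omega` (uniform over correlation matrices),
half-t(df = 3, scale = 10) on the random-effect SDs, Cauchy(0, 5) on drift
means, Cauchy(0, 2.5) on drift differences.  The source analysis states
only that the remaining fixed-effect priors were weakly informative; this
package uses Cauchy(1.5, 2.5) for boundary separation and Cauchy(0.3, 2.5)
for non-decision time (plausible centres on the seconds/evidence scale),
both overridable through `PriorSpec`.  An implied `a <= 0`, `t0 < 0`, or a
trial faster than its subject's `t0` sends the log posterior to `-inf`
rather than raising, so the sampler can traverse the unconstrained space.

`Omega` is optionally block-structured (correlations within drift,
boundary and non-decision blocks only), the cheaper structure used in the
original analyses of some datasets to reduce estimation time.

## Sampling

No probabilistic-programming backend is used: the package ships its own
No-U-Turn sampler (multinomial variant) with dual-averaging step-size
adaptation (target acceptance 0.8) and diagonal mass-matrix estimation in
Stan-style expanding warmup windows.  The hierarchical scales use a
non-centered parametrization (`u_s = diag(tau) L z_s`, standard-normal
innovations times the correlation Cholesky factor), `tau` is sampled on
the log scale, and `Omega` through tanh-transformed canonical partial
correlations, so every draw is a valid correlation matrix by construction.
All gradients — including the reverse pass through the Cholesky/partial-
correlation construction — are hand-derived and verified against finite
differences at 1e-5 relative tolerance in the suite.  Sampling a flat
likelihood reproduces the LKJ(1) marginals (the probability of an
all-positive 3x3 correlation matrix, about 0.16, is recovered by the
sampler itself as well as by direct Monte Carlo).

Convergence is gated on split R-hat < 1.05 over all fixed effects,
random-effect SDs and correlations; `fit(max_refits=...)` re-runs with
doubled post-warmup draws while the gate fails, mirroring the
refit-until-converged schedule of the original analysis (4 chains x 500
warmup + 500 draws as the base schedule).

## Posterior-predictive checks

For each selected posterior draw a dataset of exactly the observed shape
is simulated at that draw's subject-level parameters.  Observed and
replicated data are reduced to per-subject mean RT (correct responses) and
accuracy per condition plus the RT/accuracy congruency effects, and
agreement is scored with the concordance correlation coefficient,

    CCC = 2 cov(x, y) / (var(x) + var(y) + (mean x - mean y)^2),

using population (1/n) moments throughout so the defining identity holds
exactly.  Subjects with missing cells are dropped pairwise per statistic.
Reported are the CCC against the posterior-predictive mean and the
2.5%/50%/97.5% quantiles of the CCC across individual replicates.

## SEM stage

The CFA engine minimises the normal-theory ML discrepancy
`F = log|Sigma| + tr(S Sigma^-1) - log|S| - p` with analytic gradients
(quasi-Newton, bound constraints for nonnegative loadings), `chi^2 =
(N - 1) F`.  Factors are orthogonal with unit variance.  Error variances
are unconstrained; negative estimates or a (near-)singular information
matrix yield the `converged_with_warnings` status rather than being
silently repaired.  Indices: CFI against the independence baseline, RMSEA
with a 90% CI from inverting the noncentral chi-square, SRMR as the RMS
residual of the correlation-metric matrices including the diagonal (zero
diagonal residuals for correlation input).  KMO is computed from
anti-image correlations.  Reliability: single-factor omega from the
standardized solution; for bifactor models, hierarchical omega of a
specific factor with the composite taken over that factor's own
indicators (the convention adopted here, since published values do not pin
it down).  Fit-status classification: good = CFI > .95 & SRMR < .08,
acceptable = CFI in [.90, .95] & SRMR < .08, else bad; for N > 250 the
RMSEA joins the rule (good < .06, acceptable .06–.08).

Because the published inputs are correlation matrices printed to two
decimals, the worked examples are fitted in the correlation metric.  Fit
statistics are scale-invariant for these model classes (asserted as a
property test), but **omega is not**: omega computed from a covariance
matrix with unequal indicator variances differs from the
correlation-metric value.  Most printed omegas agree with the
correlation-metric recomputation to ~0.01–0.03; the Dataset 6
three-task boundary model is the clearest exception, plausibly because
that dataset's response windows differed strongly across tasks, making
task variances unequal.

Across-draw SEM: covariance matrices are subsampled from the posterior
(evenly spaced after a seed-based rotation — the original rule is not
stated), each fitted from a cold start, classified, and the reliability
distribution collected over draws with acceptable-or-good fit only.
Exceedance tables report, per threshold, the posterior probability that
the average pairwise correlation and that all pairwise correlations exceed
it (strict inequalities), with default threshold grids {0,...,.5} and
{0,...,.3}.

## Synthetic data

The generator draws per-subject parameters from exactly the multivariate
normal the model assumes and trials from the Wiener process, so every
pipeline stage can be scored against known truth.  Defaults describe a
realistic desk-scale conflict-task study: 60 subjects, 3 tasks,
congruent/incongruent, 150 trials per cell, drift mean 3.0, congruency
effect 0.8 (drift units), boundary 1.3, non-decision 0.3 s, random-effect
SDs (0.6, 0.3, 0.25, 0.05) — values in the range typical of young-adult
conflict-task fits, giving ~90% accuracy and plausible RT distributions.
Attentional-control structure is planted through the correlation of the
drift-difference random effects (`delta_corr`; 0.49 corresponds to a
single factor with loadings 0.7).  Subjects whose drawn effects imply an
invalid `a` or `t0` are redrawn (up to 100 attempts); scenarios needing
resampling for more than 5% of subjects are rejected as infeasible.

What the generator does *not* emulate: sequential dependencies
(post-error slowing, conflict adaptation), contaminant responses, response
windows/censoring, or any task-specific phenomenology.  Passing recovery
tests therefore shows the inference machinery is correct under its own
assumptions, not that real conflict-task data satisfy them.

## Problem sizes used by the test suite

Full-scale fits of this model class take weeks; the suite runs the same
pipeline at desk scale.  Parameter-recovery and planted/null factor
contrast use 16 subjects, 3 tasks, 24 trials per cell, 2 chains x 200
warmup + 200 draws (tree depth capped at 9); smoke tests use even smaller
scenarios.  The recovery assertions are correspondingly modest: credible
intervals must cover the planted correlation for at least 2 of 3 task
pairs, and the planted-factor reliability distribution must dominate the
null one.  The SEM worked examples and the LKJ baseline are exact-scale
recomputations and take seconds.

## Known limitations

- Omega values recomputed from printed correlation matrices can deviate
  from values computed on the underlying covariance matrices (above).
- The NUTS implementation is compact: diagonal mass matrix only, no
  cross-chain adaptation; stiff posteriors (non-decision times close to
  the fastest responses) force small step sizes, so desk-scale fits are
  minutes, not seconds.
- Condition-specific boundary/non-decision parameters are intentionally
  not implemented (the original attempt failed to converge and the model
  class was rejected); the bifactor route covers condition-level drift
  structure instead.
- `ConvergenceReport` monitors group-level parameters; subject-level
  displacements are not R-hat-gated by default.
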