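# Methods

This note documents the models implemented in `frailtydynamics`, the
assumptions behind them, the synthetic-data generators used to test them,
and the numerical choices that shaped the implementation.

## Damage and repair of binary health deficits

The package works with longitudinal panels of `N` binarized health
deficits per subject. At each visit the Frailty Index (FI) is `f = n/N`,
the fraction of deficits present. Between consecutive visits `t_j` and
`t_{j+1}` we count deficits that became damaged (`0 -> 1`, `n_d`) and
repaired (`1 -> 0`, `n_r`); the counts obey
`n(t_{j+1}) = n(t_j) + n_d - n_r` exactly. Damage and repair rates —
probabilities per available deficit per unit time — operationalize
*robustness* (resisting damage, low `lambda_d`) and *resilience*
(recovering from damage, high `lambda_r`).

Counts are modelled as Poisson with interval-constant rates:

    n_r(t_j) ~ Poisson( n(t_j)      * lambda_r(t_j) * dt_j )
    n_d(t_j) ~ Poisson( (N - n(t_j)) * lambda_d(t_j) * dt_j )

Rates are positive through a Softplus link, `lambda = log(1 + e^eta)`,
chosen over `exp` because it is asymptotically linear and does not
amplify covariate effects at high rates.

## Mouse joint longitudinal–survival model

Link-scale rates are linear in standardized covariates
`x(t) = (1, t, sex, treatment, f, a0, sex*treatment, sex*t, treatment*t,
sex*treatment*t)` plus correlated subject random intercepts and slopes
for both processes, `b_i = (b0_r, b1_r, b0_d, b1_d)` with covariance
`diag(sigma) Omega diag(sigma)`. Mortality is proportional hazards:

    h_i(t) = h0(t, sex) * exp( gamma.u_i + gamma_r eta_r(t) + gamma_d eta_d(t) )

with `u = (1, sex, treatment, sex*treatment, f, a0)` and sex-specific
baselines `h0 = sum_l a_l M_l(t)` built from order-3 M-splines with
simplex weights, so each baseline is a hazard *shape* (integrating to 1
over the knot span) and the overall level is carried by the survival
intercept. The link-scale rates (`eta = softplus^-1(lambda)`) feed the
hazard, so `gamma_r` and `gamma_d` measure how resilience and robustness
load on mortality at fixed FI. Cumulative hazards use 5-point
Gauss–Legendre quadrature per observed interval (exact through degree-9
polynomials); past the last visit the linear predictors extrapolate
linearly in `t` with the FI frozen at its last observed value.

Priors: N(0,3) intercepts, N(0,1) coefficients, half-Cauchy(0,1)
random-effect SDs, LKJ(2) correlation, Dirichlet(1) baseline simplexes.
Covariates are standardized to mean 0, SD 1 before interactions are
formed, so these scales are comparable across terms.

Knots: 17 knots at the minimum, maximum and 15 evenly spaced quantiles
(0.05–0.95) of last-follow-up times. A clamped order-3 M-spline family on
K distinct knots carries K+1 basis functions, so the simplex has 18
components. When heavy censoring ties the follow-up times so the quantile
rule degenerates, an evenly spaced 17-knot grid is substituted with a
warning.

Subjects with fewer than two visits carry no interval information and are
excluded from both likelihood parts (they are also removed by the
pre-processing rules).

## Human varying-coefficient model

Human cohorts are larger and need non-linear wealth x baseline-age
structure. Four coefficient surfaces per process (`base`, `x sex`,
`x t`, `x sex*t`) are tensor-product order-3 B-splines over (wealth,
baseline age) with knots at the minimum, terciles and maximum of each
variable — 4 distinct knot values give exactly 5 clamped basis functions
per axis, hence 5x5 coefficient grids. Each grid has a 2D random-walk
smoothing prior: corner cell N(0,1), first row/column one-sided walks,
interior cells a two-component density mixture
`p_w N(s[i-1,j], tau_w) + p_a N(s[i,j-1], tau_a)` with per-surface
`(p_w, p_a) ~ Dirichlet(1.5)` and half-normal(0,1) step scales. Only
subject random *intercepts* are used: with short follow-up series, random
slopes overfit, visible as residual credible-interval coverage rising
toward 0.99–1.00.

Two parameterization choices matter for sampling:

* The global intercept, `t`, `sex`, wealth and age fixed effects (and
  their `t` interactions) lie exactly in the span of the four surfaces
  and their multipliers. Sampling them as a separate block leaves the
  posterior degenerate along prior-only ridges, which stalls any sampler;
  the implementation therefore samples the identified parameterization —
  surfaces plus the FI-interaction fixed effects `(f, sex*f, w*f, a0*f)`
  only. The linear-predictor span, and hence the model, is unchanged.
* The walk scales are parameterized `tau = 0.05 + exp(ltau)`. Without
  the floor, data favouring perfectly flat surfaces pull `tau -> 0` and
  open a funnel that collapses the step size; the floor caps the funnel
  while leaving any realistic smoothness level reachable.

## Posterior computation

No probabilistic-programming framework is used: all models share an
in-house Hamiltonian Monte Carlo engine with hand-derived analytic
gradients (verified against finite differences in the test suite to
~1e-8 relative error). The sampler uses dual-averaging step-size
adaptation (target acceptance 0.85–0.9), diagonal mass-matrix adaptation
during warmup, and trajectory lengths drawn uniformly up to a cap
(24 leapfrog steps for the mouse and state-survival models, 48 for the
human model) to avoid resonance. Constrained parameters are sampled in
unconstrained space: simplexes by stick-breaking, correlation matrices by
tanh canonical partial correlations (with an analytic triangular-Jacobian
LKJ pullback), scales on the log scale. Convergence is summarized with
split-R-hat and bulk ESS (arviz); fits raise a `ConvergenceError` by
default when any fixed effect has R-hat > 1.05.

Default chain lengths are desk-scale (hundreds to ~a thousand of warmup
and sampling iterations, two chains); serious applications should raise
them. All sampling is deterministic given the integer seed.

## Derived quantities

Per posterior draw, for a covariate profile, the FI trajectory solves
`df/dt = (1-f) lambda_d - f lambda_r` (classic deficit-balance dynamics)
by RK4, with the FI feeding back into the rates. Rate time-slopes follow
the chain rule `d lambda/dt = (d eta/dt + d eta/df * df/dt) *
sigmoid(eta)`. The FI curvature splits into

    damage (robustness) term:  (1-f) dlambda_d/dt - (df/dt) lambda_d
    repair (resilience) term:  -( f dlambda_r/dt + (df/dt) lambda_r )

whose sum equals `d^2 f/dt^2` exactly per draw (an algebraic identity the
tests verify against a numeric second difference of the integrated
trajectory). Robustness dominance is summarized by the posterior
probability that `damage term - |repair term|` is negative — below 0.05
means robustness decline drives the acceleration. Spearman rank
correlations between rates and age are computed per draw at the observed
subject-interval ages; log hazard ratios per 1 SD use the SD of the
link-scale rates over subject-intervals at posterior-median parameters.

## Deficit-state survival

Each maximal run of a deficit in one state that *begins at an observed
transition* opens a state lifetime; exit transitions are interval-censored
between the flanking visits and death/drop-out right-censors. Runs
already in-state at the first visit are excluded (left-truncated onset).
The entry clock starts at the first visit observed in the new state; a
midpoint-entry option is exposed for sensitivity. Repeated spells from
the same subject/deficit are pooled as independent — a simplifying
assumption users should keep in mind.

The Bayesian model is `h(t) = e^{gamma0} sum_l a_l M_l(t)` with
Dirichlet(1) simplex weights and N(0,10) on `gamma0`; 32 knots at 30
quantiles (0.1–0.9) of representative event times (interval midpoints;
censoring times for censored records) plus the minimum and maximum, span
extended to 0 so early hazard is not extrapolated. The likelihood is
`S(T)^c [S(T_lower) - S(T_upper)]^(1-c)`, computed with I-splines
(closed-form cumulative hazards) and log-diff-exp stabilization.

The nonparametric companion is a Turnbull NPMLE (self-consistency EM over
the Turnbull intervals). Group differences use a generalized log-rank
score — observed minus expected event mass per Turnbull interval under
the pooled NPMLE, with fractional at-risk sets — whose null distribution
comes from permuting group labels (two-sided p-value with the +1
correction). The permutation approach gives exact finite-sample validity
for any interval-censoring pattern.

## Synthetic cohorts

The generators define the conditions under which the pipeline is tested.

*Mouse-like cohort* (defaults): 124 binary items (the 31-deficit clinical
frailty index expanded 4-fold), 8 visits 1.5 months apart, baseline age
16–18 months, equal sex and treatment assignment, initial per-item damage
probability 0.18. Repair rates start near 0.25/month and decline; damage
rates start near 0.02/month and rise; both depend on the current FI.
Random effects (intercept/slope x repair/damage) have SDs
(0.25, 0.03, 0.35, 0.04) with a moderate correlation structure. Mortality
has a piecewise-constant, sex-specific baseline rising from ~0.05 to
~0.3 per month over follow-up, multiplied by FI and link-scale rate
loadings (`gamma_r = -0.3`, `gamma_d = +0.5`), yielding roughly half the
cohort dying during follow-up — realistic for aging mice.

Transitions are simulated per item as Bernoulli events with the exact
exponential-interval probability `1 - exp(-lambda dt)` (rates evaluated
at interval start, explicit-Euler FI feedback), so counts can never
exceed available items; the Poisson likelihood is this process's
small-rate limit. Death times are drawn by exact inverse-transform
sampling of the piecewise `h0 exp(c + m t)` cumulative hazard. One
integer seed drives everything through spawned per-subject streams.

Because the generator is Bernoulli and the fit is Poisson with
interval-start rates, the fit's estimand at repair-scale rates
(`lambda dt ~ 0.4`) is the discretized effective rate
`(1 - e^{-lambda dt})/dt` rather than `lambda` itself. Parameter-recovery
tests therefore compare posteriors against the effective-rate linear
predictor projected onto the fitted (standardized) design — the exact
estimand of the fit under the generating process. A separate
Poisson-consistent generator (`simulate_poisson_counts`) draws counts
directly from the fitted likelihood and is used for calibration checks
(residual coverage), where the model must be its own data-generating
process.

*Human-like cohort*: 23 ADL/IADL items, 7 waves 2 years apart, baseline
ages 50–88, log-scale wealth ~ N(0,1), linear generating effects (so the
generating surfaces are flat — a known-truth regime for surface
recovery), subject random intercepts only, no mortality.

What the generators do **not** emulate: measurement error beyond what
pruning addresses, deficit heterogeneity (all items share the same
rates), visit-schedule irregularity, informative drop-out other than
death, and recruitment effects. Passing recovery tests therefore shows
the estimators work when their assumptions hold, not that those
assumptions hold in any particular real dataset.

## Pre-processing rules

Mouse panels: LOCF imputation (forward, then leading values backward;
fully-missing series are an error); fractional scores on the quarter grid
expand to 4 ordered binary items each (`0.75 -> [1,1,1,0]`), preserving
every FI value exactly and turning a 31 (29)-item index into 124 (116)
binary items; visits closer than `min_gap` or farther than `max_gap` from
the previous retained visit are dropped (the later visit of an offending
pair is removed and gaps re-evaluated against the last retained visit);
subjects with fewer than two remaining visits are dropped. Human panels:
baseline age restricted to [50, 89], inter-wave gaps above 4 years and
subjects with fewer than 6 waves dropped, imputed-wealth subjects
dropped, wealth transformed `w = log(w_raw + mean(w_raw))` with the mean
over retained subjects (computed after all other filters). The
sensitivity pruning flattens exactly the single-visit excursions
`x,x,!x,x,x -> x,x,x,x,x`; it is idempotent and never creates
transitions.

## Model criticism

Posterior predictive checks draw replicate counts per draw. Residual
calibration uses a randomized probability integral transform (counts are
discrete, so plain predictive intervals over-cover mechanically): under a
well-calibrated fit the PIT is uniform and 95% coverage sits near 0.95.
Coverage at 0.99–1.00 flags overfitting. Bayesian R² per draw is
`Var(mu) / (Var(mu) + Var(y - mu))`. Note that on Bernoulli-generated
cohorts the Poisson model genuinely over-disperses (binomial counts have
smaller variance), so coverage runs slightly conservative there; the
calibration test uses the Poisson-consistent generator.

## Problem sizes in the test suite

The automated suite runs everything at desk scale, chosen to exercise the
full machinery: recovery uses 5 replicate cohorts of 60 subjects x 8
visits with 600+600 iterations x 2 chains (coverage threshold >= 90% of
parameter-replicate pairs); the interval-censored check uses 500 records;
log-rank calibration uses 200 null replicates at 499 permutations and
power uses 40 replicates at 200 per group. Larger cohorts and the
full-length chains are a matter of passing different arguments.

## Known limitations

* Plain HMC with jittered trajectory lengths is less adaptive than a
  dynamic-trajectory (NUTS-style) sampler; strongly correlated posteriors
  need the longer trajectory caps used here, and very small cohorts can
  still show slow mixing for survival-block parameters.
* The Poisson interval likelihood ignores within-interval state changes
  (net counts only) and under-weights fast oscillation; both fitted rates
  are net rates at the visit cadence.
* The state-survival pooling of repeated spells ignores within-subject
  correlation; p-values from the permutation log-rank are exact only
  under exchangeability of records across groups.
* The hazard beyond the baseline-spline knot span is clamped to its
  boundary value.
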