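# frailtydynamics

Damage and repair dynamics of binarized health deficits in aging cohorts.

Aging health is often summarized by the Frailty Index (FI), the fraction
`f = n/N` of a fixed list of `N` binary health deficits an individual
currently has. The FI hides the two processes that move it: *damage*
(`0 -> 1` transitions, whose per-item rate `lambda_d` measures loss of
robustness) and *repair* (`1 -> 0` transitions, rate `lambda_r`,
measuring resilience). Given longitudinal panels of deficit states —
mouse clinical frailty index assessments every few weeks, or ADL/IADL
items over biennial human survey waves — this package separates and
models those processes:

* **Transition counting** — per-interval damaged/repaired counts
  satisfying `n(t_{j+1}) = n(t_j) + n_d - n_r` exactly, plus binned
  nonparametric rate estimates with standard errors.
* **Mouse joint longitudinal–survival model** — Poisson counts with
  Softplus-linear rates `lambda = log(1 + e^eta)`,
  `eta = beta.x(t) + b_{i0} + b_{i1} t`, correlated 4-dimensional subject
  random effects (LKJ prior), coupled to a proportional-hazards survival
  model `h_i(t) = h0(t, sex) exp(gamma.u_i + gamma_r eta_r + gamma_d
  eta_d)` with sex-specific M-spline baseline hazards.
* **Human varying-coefficient model** — rate surfaces over (wealth,
  baseline age) as tensor-product B-splines with 2D random-walk
  smoothing priors, subject random intercepts, no survival component.
* **Derived quantities** — FI trajectories `df/dt = (1-f) lambda_d -
  f lambda_r`, rate time-slopes, the FI curvature split exactly into
  robustness and resilience terms, posterior Spearman rate-age
  correlations, and log hazard ratios per SD of each rate.
* **Deficit-state survival** — interval/right-censored lifetimes of
  damaged and undamaged states, a Bayesian M-spline hazard model, the
  Turnbull NPMLE, and a permutation generalized log-rank test.
* **Synthetic cohorts** — generators with known ground truth (per-item
  Bernoulli transitions, exact inverse-transform mortality) for every
  pipeline stage and for parameter-recovery studies.

All Bayesian models are sampled with a built-in Hamiltonian Monte Carlo
engine (analytic gradients, dual-averaging step sizes, diagonal mass
adaptation) and diagnosed with split-R-hat/ESS. See `docs/methods.md`
for the models, priors, and numerical choices.

## Worked example

```python
import numpy as np
from frailtydynamics import (
    GroundTruth, simulate_cohort, count_transitions, MouseJointModel,
    build_rate_curve, curvature_terms, hazard_ratio_per_sd,
)

truth = GroundTruth()                       # mouse-like defaults
cohort = simulate_cohort(truth, n_subjects=60, seed=11)
counts = count_transitions(cohort.panel)
model = MouseJointModel(counts, cohort.panel.survival)
results = model.fit(n_warmup=600, n_samples=600, n_chains=2, seed=5,
                    on_bad_convergence="warn")
print(results.summary(diagnostics=False).head(3)[["parameter", "mean", "q2.5", "q97.5"]])

hr = hazard_ratio_per_sd(results)
print("log HR per SD (damage):", round(hr["log_hr_damage"].median(), 2))
print("log HR per SD (repair):", round(hr["log_hr_repair"].median(), 2))

curve = build_rate_curve(results, {"sex": 0.0, "treatment": 0.0, "a0": 17.0},
                         np.linspace(0, 10, 60), f0=0.18)
cd = curvature_terms(curve)
print("late-life damage term:", round(float(np.median(cd.damage_term[:, -1])), 5))
print("late-life repair term:", round(float(np.median(cd.repair_term[:, -1])), 5))
```

Typical output (seed 11/5):

```
   parameter      mean      q2.5     q97.5
0  beta_r[0] -1.678508 -1.746027 -1.613390
1  beta_r[1] -0.078387 -0.129016 -0.023161
2  beta_r[2] -0.053138 -0.137981  0.023019
log HR per SD (damage): 0.67
log HR per SD (repair): -0.19
late-life damage term: 0.00173
late-life repair term: -2e-05
```

Reading this: the repair-rate intercept `beta_r[0]` is the link-scale
repair rate at reference covariates (softplus(-1.68) ~ 0.17 per item per
month); its negative time coefficient `beta_r[1]` is declining resilience
with age. A one-SD higher damage rate raises the death hazard by
`e^0.67 ~ 2x` while a one-SD higher repair rate lowers it, and the
positive damage curvature term dwarfing the repair term's magnitude says
declining robustness, more than declining resilience, drives the
late-life acceleration of the FI — the pattern the synthetic truth was
built to show.

A `frailtydynamics` command-line interface wraps the stages
(`simulate`, `counts`, `fit-mouse`, `fit-human`, `state-survival`,
`report`, `run-pipeline` with a YAML config); every stage reads and
writes plain CSV.

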