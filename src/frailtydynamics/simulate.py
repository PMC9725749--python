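"""Synthetic cohorts with known damage/repair dynamics and mortality.

The generator mirrors the fitted models as a valid stochastic process: at
each inter-visit interval every damaged item repairs independently with the
exact exponential-interval probability ``1 - exp(-lambda_r dt)`` and every
undamaged item damages with ``1 - exp(-lambda_d dt)``, with rates from the
Softplus-linear predictor evaluated at the interval start (explicit-Euler
convention for the FI feedback). Mortality follows a proportional-hazards
model with a piecewise-constant sex-specific baseline and log-hazard
loadings on the link-scale (inverse-Softplus) repair and damage rates;
death times are drawn by exact inverse-transform sampling of the cumulative
hazard, which is piecewise ``h0 * exp(c + m t)`` and integrable in closed
form. Per-item Bernoulli transitions (rather than aggregate Poisson draws)
guarantee counts can never exceed available items; the Poisson likelihood
used for fitting is the small-rate limit of this process.

One integer seed governs everything through a splittable ``SeedSequence``;
per-subject streams are spawned deterministically, so cohorts are
reproducible and subjects are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import human_raw_design, mouse_raw_design, mouse_raw_survival_design
from .links import softplus
from .panel import DeficitPanel

__all__ = [
    "GroundTruth", "SimulatedCohort", "SubjectState",
    "simulate_cohort", "simulate_survival",
    "HumanGroundTruth", "simulate_human_cohort",
]


class ScheduleError(ValueError):
    pass


class DefinitenessError(ValueError):
    pass


def _default_schedule():
    # 8 visits, 1.5-month (~6-week) spacing
    return np.arange(0.0, 12.0, 1.5)


def _default_beta_r():
    # raw-design order: 1, t, sex, treat, f, a0, sex*treat, sex*t, treat*t, sex*treat*t
    return np.array([-1.35, -0.08, -0.25, 0.10, 0.60, 0.0, 0.0, 0.03, 0.04, 0.0])


def _default_beta_d():
    return np.array([-3.90, 0.09, 0.30, -0.10, 0.80, 0.0, 0.0, 0.02, -0.04, 0.0])


@dataclass
class GroundTruth:
    """Generating parameters for a synthetic cohort.

    Coefficients act on the raw-covariate design (time in the panel's time
    unit from baseline, sex/treatment 0-1 indicators, FI in [0,1], baseline
    age in the same unit); rates come out through the Softplus link, per
    item per unit time. Random effects ``(b0_r, b1_r, b0_d, b1_d)`` have
    standard deviations ``re_sd`` and correlation ``re_corr``. The survival
    component loads on covariates ``u = (1, sex, treatment, sex*treatment,
    f, a0)`` via ``gamma`` and on the link-scale rates via ``gamma_r`` and
    ``gamma_d``; its baseline hazard is piecewise-constant per sex on
    ``base_hazard_edges``.
    """

    beta_r: np.ndarray = field(default_factory=_default_beta_r)
    beta_d: np.ndarray = field(default_factory=_default_beta_d)
    re_sd: np.ndarray = field(default_factory=lambda: np.array([0.25, 0.03, 0.35, 0.04]))
    re_corr: np.ndarray = field(default_factory=lambda: np.array([
        [1.0, -0.2, 0.3, 0.0],
        [-0.2, 1.0, 0.0, 0.1],
        [0.3, 0.0, 1.0, -0.2],
        [0.0, 0.1, -0.2, 1.0],
    ]))
    gamma: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.3, -0.2, 0.0, 0.8, 0.0]))
    gamma_r: float = -0.3
    gamma_d: float = 0.5
    base_hazard_edges: np.ndarray = field(default_factory=lambda: np.array([0.0, 4.0, 8.0, 12.0]))
    base_hazard_male: np.ndarray = field(default_factory=lambda: np.array([0.05, 0.12, 0.25]))
    base_hazard_female: np.ndarray = field(default_factory=lambda: np.array([0.07, 0.16, 0.30]))
    n_items: int = 124
    schedule: np.ndarray = field(default_factory=_default_schedule)
    initial_damage_prob: float = 0.18
    sex_prob: float = 0.5
    treatment_prob: float = 0.5
    baseline_age_range: tuple = (16.0, 18.0)

    def __post_init__(self):
        for name in ("beta_r", "beta_d", "re_sd", "re_corr", "gamma",
                     "base_hazard_edges", "base_hazard_male", "base_hazard_female",
                     "schedule"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        if np.any(np.diff(self.schedule) <= 0):
            raise ScheduleError("visit schedule must be strictly increasing")
        if np.any(self.re_sd < 0):
            raise DefinitenessError("random-effect SDs must be non-negative")
        C = self.re_corr
        if C.shape != (4, 4) or not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise DefinitenessError("re_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(C).min() <= 1e-10:
            raise DefinitenessError("re_corr must be positive-definite")
        if np.any(self.base_hazard_male < 0) or np.any(self.base_hazard_female < 0):
            raise ValueError("baseline hazards must be non-negative")

    def re_cholesky(self) -> np.ndarray:
        sd = np.where(self.re_sd > 0, self.re_sd, 1e-12)
        return np.linalg.cholesky(np.diag(sd) @ self.re_corr @ np.diag(sd))

    # ---------------------------------------------------------------- config

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}
        d["baseline_age_range"] = list(self.baseline_age_range)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "GroundTruth":
        d = yaml.safe_load(Path(path).read_text())
        d["baseline_age_range"] = tuple(d["baseline_age_range"])
        return cls(**d)


@dataclass
class SubjectState:
    """Per-interval linear predictors and FI for one subject's follow-up.

    ``eta_*[j]`` is the link-scale rate at visit ``times[j]`` with the FI
    frozen at that visit; within ``[t_j, t_{j+1})`` the predictor evolves
    linearly with slope ``eta_*_slope[j]``.
    """

    times: np.ndarray
    fi: np.ndarray
    eta_r: np.ndarray
    eta_d: np.ndarray
    eta_r_slope: np.ndarray
    eta_d_slope: np.ndarray
    sex: float
    treatment: float
    baseline_age: float


@dataclass
class SimulatedCohort:
    panel: DeficitPanel
    true_rates: pd.DataFrame
    truth: GroundTruth
    seed: int


def _base_hazard_fn(truth: GroundTruth, sex: float):
    vals = truth.base_hazard_female if sex >= 0.5 else truth.base_hazard_male
    edges = truth.base_hazard_edges

    def h0(t):
        i = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(vals) - 1)
        return vals[i]

    return h0, edges, vals


def simulate_survival(truth: GroundTruth, state: SubjectState, seed) -> tuple[float, int]:
    """Draw a death/censoring time for one subject by inverse-transform.

    The hazard is ``h0(t, sex) * exp(gamma.u + gamma_r eta_r(t) +
    gamma_d eta_d(t))`` with ``eta`` piecewise-linear; within each piece the
    cumulative hazard is available in closed form and is inverted exactly.
    Subjects surviving past the last visit are right-censored there.

    Returns ``(time, censored)`` with ``censored = 1`` for censoring.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h0fn, edges, vals = _base_hazard_fn(truth, state.sex)
    target = rng.exponential()
    times = state.times
    t0 = times[0]
    acc = 0.0
    for j in range(len(times) - 1):
        t1, t2 = times[j], times[j + 1]
        u = mouse_raw_survival_design(
            state.sex, state.treatment, state.fi[j], state.baseline_age
        )[0]
        c_lin = (
            float(truth.gamma @ u)
            + truth.gamma_r * (state.eta_r[j] - state.eta_r_slope[j] * t1)
            + truth.gamma_d * (state.eta_d[j] - state.eta_d_slope[j] * t1)
        )
        m = truth.gamma_r * state.eta_r_slope[j] + truth.gamma_d * state.eta_d_slope[j]
        # split [t1, t2) at baseline-hazard edges
        cuts = np.concatenate(([t1], edges[(edges > t1) & (edges < t2)], [t2]))
        for a, b in zip(cuts[:-1], cuts[1:]):
            h0 = h0fn(0.5 * (a + b))
            if h0 <= 0:
                continue
            scale = h0 * np.exp(c_lin)
            if abs(m) < 1e-12:
                seg = scale * np.exp(m * a) * (b - a)
                if acc + seg >= target:
                    return float(a + (target - acc) / (scale * np.exp(m * a))), 0
            else:
                seg = scale / m * (np.exp(m * b) - np.exp(m * a))
                if acc + seg >= target:
                    t_death = np.log(np.exp(m * a) + m * (target - acc) / scale) / m
                    return float(t_death), 0
            acc += seg
    return float(times[-1]), 1


def simulate_cohort(truth: GroundTruth, n_subjects: int, seed: int) -> SimulatedCohort:
    """Generate a full synthetic cohort (panel + survival + true rates)."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    truth.validate()
    streams = np.random.SeedSequence(seed).spawn(n_subjects)
    N = truth.n_items
    L = truth.re_cholesky()
    obs_rows, rate_rows, surv_rows, cov_rows = [], [], [], []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        sid = f"s{i:04d}"
        sex = float(rng.random() < truth.sex_prob)
        treatment = float(rng.random() < truth.treatment_prob)
        a0 = float(rng.uniform(*truth.baseline_age_range))
        b = L @ rng.standard_normal(4)  # b0_r, b1_r, b0_d, b1_d
        states = (rng.random(N) < truth.initial_damage_prob).astype(float)
        times = truth.schedule
        J = len(times)
        state_mat = np.empty((J, N))
        fi = np.empty(J)
        eta_r = np.empty(J)
        eta_d = np.empty(J)
        slope_r = np.empty(max(J - 1, 1))
        slope_d = np.empty(max(J - 1, 1))
        for j in range(J):
            state_mat[j] = states
            f = states.mean()
            fi[j] = f
            x = mouse_raw_design(times[j], sex, treatment, f, a0)[0]
            eta_r[j] = truth.beta_r @ x + b[0] + b[1] * times[j]
            eta_d[j] = truth.beta_d @ x + b[2] + b[3] * times[j]
            if j < J - 1:
                # d eta / dt with f frozen: explicit time terms + random slope
                slope_r[j] = (
                    truth.beta_r[1] + truth.beta_r[7] * sex + truth.beta_r[8] * treatment
                    + truth.beta_r[9] * sex * treatment + b[1]
                )
                slope_d[j] = (
                    truth.beta_d[1] + truth.beta_d[7] * sex + truth.beta_d[8] * treatment
                    + truth.beta_d[9] * sex * treatment + b[3]
                )
                dt = times[j + 1] - times[j]
                lam_r = softplus(eta_r[j])
                lam_d = softplus(eta_d[j])
                p_rep = -np.expm1(-lam_r * dt)
                p_dam = -np.expm1(-lam_d * dt)
                u = rng.random(N)
                damaged = states == 1
                states = states.copy()
                states[damaged & (u < p_rep)] = 0.0
                states[~damaged & (u < p_dam)] = 1.0
        subj = SubjectState(
            times=times, fi=fi, eta_r=eta_r, eta_d=eta_d,
            eta_r_slope=slope_r, eta_d_slope=slope_d,
            sex=sex, treatment=treatment, baseline_age=a0,
        )
        death_time, censored = simulate_survival(truth, subj, rng)
        observed = times <= death_time + 1e-12
        for j in np.where(observed)[0]:
            obs_rows.append(pd.DataFrame({
                "subject_id": sid,
                "time": times[j],
                "deficit_id": [f"d{k:03d}" for k in range(N)],
                "value": state_mat[j],
            }))
            rate_rows.append({
                "subject_id": sid, "time": times[j], "fi": fi[j],
                "eta_r": eta_r[j], "eta_d": eta_d[j],
                "lambda_r": float(softplus(eta_r[j])),
                "lambda_d": float(softplus(eta_d[j])),
            })
        cov_rows.append({
            "subject_id": sid, "sex": sex, "treatment": treatment,
            "baseline_age": a0,
            "b0_r": b[0], "b1_r": b[1], "b0_d": b[2], "b1_d": b[3],
        })
        surv_rows.append({
            "subject_id": sid, "death_time": death_time, "censored": censored,
        })
    panel = DeficitPanel(
        observations=pd.concat(obs_rows, ignore_index=True),
        covariates=pd.DataFrame(cov_rows).set_index("subject_id")[
            ["sex", "treatment", "baseline_age"]
        ],
        survival=pd.DataFrame(surv_rows).set_index("subject_id"),
        time_unit="months",
    )
    true_re = pd.DataFrame(cov_rows).set_index("subject_id")[
        ["b0_r", "b1_r", "b0_d", "b1_d"]
    ]
    cohort = SimulatedCohort(
        panel=panel,
        true_rates=pd.DataFrame(rate_rows),
        truth=truth,
        seed=seed,
    )
    cohort.true_random_effects = true_re
    return cohort


# ---------------------------------------------------------------- human arm

def _default_hbeta_r():
    # raw human design: 1, t, sex, w, f, a0, sex*t, w*t, a0*t, sex*f, w*f, a0*f
    return np.array([0.10, -0.030, -0.15, 0.15, 0.4, -0.022,
                     0.0, 0.0, 0.0, 0.0, 0.0, 0.0])


def _default_hbeta_d():
    return np.array([-5.85, 0.040, 0.10, -0.12, 0.8, 0.030,
                     0.0, 0.0, 0.0, 0.0, 0.0, 0.0])


@dataclass
class HumanGroundTruth:
    """Generating parameters for an ELSA-like human cohort.

    Time in years, ~2-year waves, 23 ADL/IADL deficits, subject random
    intercepts only, no mortality (all subjects censored at their last
    wave). Wealth is on the log-transformed scale used for modelling.
    """

    beta_r: np.ndarray = field(default_factory=_default_hbeta_r)
    beta_d: np.ndarray = field(default_factory=_default_hbeta_d)
    re_sd: np.ndarray = field(default_factory=lambda: np.array([0.30, 0.40]))
    re_rho: float = 0.2
    n_items: int = 23
    schedule: np.ndarray = field(default_factory=lambda: np.arange(0.0, 14.0, 2.0))
    initial_damage_prob: float = 0.06
    sex_prob: float = 0.5
    baseline_age_range: tuple = (50.0, 88.0)
    wealth_mean: float = 0.0
    wealth_sd: float = 1.0

    def __post_init__(self):
        for name in ("beta_r", "beta_d", "re_sd", "schedule"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.schedule) <= 0):
            raise ScheduleError("visit schedule must be strictly increasing")
        if not -1 < self.re_rho < 1:
            raise DefinitenessError("re_rho must lie in (-1, 1)")

    def re_cholesky(self) -> np.ndarray:
        C = np.array([[1.0, self.re_rho], [self.re_rho, 1.0]])
        sd = np.where(self.re_sd > 0, self.re_sd, 1e-12)
        return np.linalg.cholesky(np.diag(sd) @ C @ np.diag(sd))


def simulate_human_cohort(truth: HumanGroundTruth, n_subjects: int, seed: int) -> SimulatedCohort:
    """Generate a human-style cohort: same per-item mechanics, no mortality."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_subjects)
    N = truth.n_items
    L = truth.re_cholesky()
    obs_rows, rate_rows, cov_rows = [], [], []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        sid = f"h{i:05d}"
        sex = float(rng.random() < truth.sex_prob)
        a0 = float(rng.uniform(*truth.baseline_age_range))
        w = float(rng.normal(truth.wealth_mean, truth.wealth_sd))
        b = L @ rng.standard_normal(2)
        states = (rng.random(N) < truth.initial_damage_prob).astype(float)
        for j, t in enumerate(truth.schedule):
            f = states.mean()
            x = human_raw_design(t, sex, w, f, a0)[0]
            eta_r = truth.beta_r @ x + b[0]
            eta_d = truth.beta_d @ x + b[1]
            obs_rows.append(pd.DataFrame({
                "subject_id": sid, "time": t,
                "deficit_id": [f"d{k:02d}" for k in range(N)],
                "value": states.copy(),
            }))
            rate_rows.append({
                "subject_id": sid, "time": t, "fi": f,
                "eta_r": eta_r, "eta_d": eta_d,
                "lambda_r": float(softplus(eta_r)),
                "lambda_d": float(softplus(eta_d)),
            })
            if j < len(truth.schedule) - 1:
                dt = truth.schedule[j + 1] - t
                p_rep = -np.expm1(-softplus(eta_r) * dt)
                p_dam = -np.expm1(-softplus(eta_d) * dt)
                u = rng.random(N)
                damaged = states == 1
                states = states.copy()
                states[damaged & (u < p_rep)] = 0.0
                states[~damaged & (u < p_dam)] = 1.0
        cov_rows.append({
            "subject_id": sid, "sex": sex, "wealth": w, "baseline_age": a0,
            "b0_r": b[0], "b0_d": b[1],
        })
    panel = DeficitPanel(
        observations=pd.concat(obs_rows, ignore_index=True),
        covariates=pd.DataFrame(cov_rows).set_index("subject_id")[
            ["sex", "wealth", "baseline_age"]
        ],
        survival=None,
        time_unit="years",
    )
    cohort = SimulatedCohort(
        panel=panel, true_rates=pd.DataFrame(rate_rows), truth=truth, seed=seed,
    )
    cohort.true_random_effects = pd.DataFrame(cov_rows).set_index("subject_id")[
        ["b0_r", "b0_d"]
    ]
    return cohort


def simulate_poisson_counts(truth: GroundTruth, n_subjects: int, seed: int):
    """Model-consistent synthetic transition counts (Poisson, not Bernoulli).

    Draws the per-interval counts directly from the Poisson likelihood the
    models fit (truncated to the available items so the conservation
    identity holds), with no mortality. Used for likelihood-calibration
    checks, where the fitted model must be the exact data-generating
    process; the cohort simulators are the more realistic (under-dispersed)
    Bernoulli processes.

    Returns ``(TransitionCounts, survival_df)`` with everyone censored at
    the last visit.
    """
    from .transitions import TransitionCounts

    streams = np.random.SeedSequence(seed).spawn(n_subjects)
    N = truth.n_items
    L = truth.re_cholesky()
    rows, surv = [], []
    times = truth.schedule
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        sid = f"p{i:04d}"
        sex = float(rng.random() < truth.sex_prob)
        treatment = float(rng.random() < truth.treatment_prob)
        a0 = float(rng.uniform(*truth.baseline_age_range))
        b = L @ rng.standard_normal(4)
        n = int(rng.binomial(N, truth.initial_damage_prob))
        for j in range(len(times) - 1):
            t = times[j]
            dt = times[j + 1] - t
            f = n / N
            x = mouse_raw_design(t, sex, treatment, f, a0)[0]
            lam_r = float(softplus(truth.beta_r @ x + b[0] + b[1] * t))
            lam_d = float(softplus(truth.beta_d @ x + b[2] + b[3] * t))
            y_r = min(int(rng.poisson(n * lam_r * dt)), n)
            y_d = min(int(rng.poisson((N - n) * lam_d * dt)), N - n)
            rows.append({
                "subject_id": sid, "time": t, "dt": dt, "n": n,
                "n_damage": y_d, "n_repair": y_r, "n_next": n + y_d - y_r,
                "sex": sex, "treatment": treatment, "baseline_age": a0,
            })
            n = n + y_d - y_r
        surv.append({"subject_id": sid, "death_time": float(times[-1]), "censored": 1})
    counts = TransitionCounts(pd.DataFrame(rows), n_items=N, time_unit="months")
    counts.validate()
    return counts, pd.DataFrame(surv).set_index("subject_id")
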