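"""Bayesian joint longitudinal-survival model for mouse damage/repair rates.

Longitudinal part: per-interval repair and damage counts are Poisson with
means ``n lambda_r dt`` and ``(N - n) lambda_d dt``, where the rates are
Softplus-linear in standardized covariates with correlated subject random
intercepts and time-slopes for both processes (4-dimensional random effect,
LKJ-correlated). Survival part: proportional hazards with sex-specific
M-spline baseline (simplex-weighted) and log-hazard loadings ``gamma_r,
gamma_d`` on the link-scale (inverse-Softplus) rates, so the longitudinal
process informs mortality. Cumulative hazards use 5-point Gauss-Legendre
quadrature on each observed interval; rate trajectories extend linearly on
the link scale past the last visit (FI frozen at its last observed value).

Subjects contributing no observed interval (fewer than two visits) are
excluded from both likelihood parts, mirroring the cohort pre-processing
rule that removes them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .design import (
    MouseDesign,
    mouse_raw_design,
    mouse_raw_survival_design,
)
from .links import softplus, softplus_derivative, softplus_inverse
from .mcmc import ConvergenceError, run_hmc
from .posterior import PosteriorDraws
from .splines import KnotError, MSplineBasis, make_knots_mouse
from .transforms import (
    corr_cholesky,
    corr_chol_grad_y,
    corr_logprior_and_grad,
    log_halfcauchy,
    stick_breaking,
    stick_breaking_vjp,
)
from .transitions import TransitionCounts

__all__ = [
    "MousePriors",
    "MouseJointModel",
    "MouseJointResults",
    "longitudinal_loglik",
    "gauss_legendre_cumhaz",
    "expected_fixed_effects",
]

FIXED_EFFECT_NAMES = ["beta_r", "beta_d", "gamma", "gamma_r", "gamma_d"]

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(5)


@dataclass
class MousePriors:
    """Prior scales: N(0,3) intercepts, N(0,1) coefficients, half-Cauchy(0,1)
    random-effect SDs, LKJ(2) correlations, Dirichlet(1) spline simplexes."""

    intercept_scale: float = 3.0
    coef_scale: float = 1.0
    re_sd_scale: float = 1.0
    lkj_eta: float = 2.0

    def __post_init__(self):
        if min(self.intercept_scale, self.coef_scale, self.re_sd_scale) <= 0:
            raise ValueError("prior scales must be positive")


def gauss_legendre_cumhaz(hfun, breakpoints) -> float:
    """5-point Gauss-Legendre integral of a hazard over consecutive segments.

    Exact for polynomials up to degree 9 within each segment.
    """
    breaks = np.asarray(breakpoints, dtype=float)
    total = 0.0
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        total += half * np.sum(_GL_WEIGHTS * hfun(mid + half * _GL_NODES))
    return float(total)


def longitudinal_loglik(counts: TransitionCounts, lambda_r, lambda_d) -> float:
    """Poisson log-likelihood of the transition counts at given rates.

    ``lambda_r``/``lambda_d`` are per-row rate arrays aligned with
    ``counts.data``. Rows with no items available for a process contribute
    zero iff their count is zero, else ``-inf``.
    """
    d = counts.data
    N = counts.n_items
    n = d["n"].to_numpy(float)
    dt = d["dt"].to_numpy(float)
    y_r = d["n_repair"].to_numpy(float)
    y_d = d["n_damage"].to_numpy(float)
    ll = 0.0
    for y, avail, lam in ((y_r, n, np.asarray(lambda_r, float)),
                          (y_d, N - n, np.asarray(lambda_d, float))):
        mu = avail * lam * dt
        pos = mu > 0
        if np.any(y[~pos] > 0):
            return -np.inf
        ll += float(np.sum(y[pos] * np.log(mu[pos]) - mu[pos] - gammaln(y[pos] + 1)))
    return ll


class MouseJointModel:
    """Joint model built from transition counts and survival records.

    Parameters
    ----------
    counts : TransitionCounts
    survival : DataFrame indexed by subject_id with ``death_time`` (time
        from baseline, same unit as the counts) and ``censored`` (1 =
        right-censored).
    priors : MousePriors
    knots : optional explicit baseline-hazard knot vector. By default the
        17-knot quantile rule on last-follow-up times is used; if the
        follow-up times are too tied for that rule (heavy censoring at a
        common end-of-study time), an evenly spaced 17-knot grid over the
        follow-up range is substituted with a warning.
    """

    def __init__(self, counts: TransitionCounts, survival: pd.DataFrame,
                 priors: MousePriors | None = None, knots=None,
                 include_survival: bool = True):
        counts.validate()
        self.counts = counts
        self.include_survival = include_survival
        self.priors = priors or MousePriors()
        self.design = MouseDesign.from_counts(counts.data, counts.n_items)
        self.N = counts.n_items
        d = counts.data
        self.n_subjects = len(self.design.subject_ids)
        if self.n_subjects < 2:
            raise ValueError("joint model requires at least 2 subjects")

        if survival.index.name != "subject_id" and "subject_id" in survival.columns:
            survival = survival.set_index("subject_id")
        missing = set(self.design.subject_ids) - set(survival.index)
        if missing:
            raise ValueError(f"survival records missing for subjects {sorted(missing)[:5]}")
        extra = set(survival.index) - set(self.design.subject_ids)
        if extra:
            warnings.warn(
                f"{len(extra)} survival records without observed intervals dropped",
                stacklevel=2,
            )
        self.survival = survival.loc[self.design.subject_ids]
        self.T = self.survival["death_time"].to_numpy(float)
        self.censored = self.survival["censored"].to_numpy(int)

        # longitudinal arrays
        self.X = self.design.X
        self.t_raw = self.design.t_raw
        self.subj = self.design.subject_index
        self.n_row = d["n"].to_numpy(float)
        self.dt = d["dt"].to_numpy(float)
        self.y_r = d["n_repair"].to_numpy(float)
        self.y_d = d["n_damage"].to_numpy(float)
        self.rep_mask = self.n_row > 0
        self.dam_mask = self.n_row < self.N

        if knots is None:
            try:
                knots = make_knots_mouse(self.T)
            except KnotError:
                warnings.warn(
                    "quantile knot rule degenerate (tied follow-up times); "
                    "using an evenly spaced 17-knot grid",
                    stacklevel=2,
                )
                lo = float(d["time"].min())
                knots = np.linspace(min(lo, self.T.min()), self.T.max(), 17)
        self.knots = np.asarray(knots, float)
        self.basis = MSplineBasis(self.knots)
        self.n_basis = self.basis.n_basis

        self._build_quadrature(d)
        self._layout()

    # ------------------------------------------------------------ structure

    def _std_rows(self, frame: pd.DataFrame):
        """Standardized longitudinal (X) and survival (U) design rows."""
        std = self.design.standardizer
        z = {c: std.transform(frame, c)
             for c in ["time", "sex", "treatment", "fi", "baseline_age"]}
        one = np.ones(len(frame))
        X = np.column_stack([
            one, z["time"], z["sex"], z["treatment"], z["fi"], z["baseline_age"],
            z["sex"] * z["treatment"], z["sex"] * z["time"],
            z["treatment"] * z["time"], z["sex"] * z["treatment"] * z["time"],
        ])
        U = np.column_stack([
            one, z["sex"], z["treatment"], z["sex"] * z["treatment"],
            z["fi"], z["baseline_age"],
        ])
        return X, U

    def _build_quadrature(self, d: pd.DataFrame):
        segs = []  # (subject_idx, t_a, t_b, fi, sex, treatment, a0)
        death_rows = []  # (subject_idx, T, fi, sex, treatment, a0)
        for si, sid in enumerate(self.design.subject_ids):
            rows = d[d["subject_id"] == sid].sort_values("time")
            T_i = self.T[si]
            sex = float(rows["sex"].iloc[0])
            treat = float(rows["treatment"].iloc[0])
            a0 = float(rows["baseline_age"].iloc[0])
            last_end = None
            for _, r in rows.iterrows():
                a, b = float(r["time"]), float(r["time"] + r["dt"])
                fi = float(r["n"]) / self.N
                segs.append((si, a, min(b, T_i), fi, sex, treat, a0))
                last_end = b
                last_fi = float(r["n_next"]) / self.N
            if T_i > last_end + 1e-12:
                segs.append((si, last_end, T_i, last_fi, sex, treat, a0))
            if self.censored[si] == 0:
                death_rows.append((si, T_i, last_fi, sex, treat, a0))

        # quadrature nodes
        node_frames, node_meta = [], []
        for (si, a, b, fi, sex, treat, a0) in segs:
            if b - a <= 1e-12:
                continue
            mid, half = 0.5 * (a + b), 0.5 * (b - a)
            ts = mid + half * _GL_NODES
            node_frames.append(pd.DataFrame({
                "time": ts, "sex": sex, "treatment": treat,
                "fi": fi, "baseline_age": a0,
            }))
            node_meta.append(pd.DataFrame({
                "subj": si, "w": half * _GL_WEIGHTS, "t": ts, "sex": sex,
            }))
        nf = pd.concat(node_frames, ignore_index=True)
        nm = pd.concat(node_meta, ignore_index=True)
        self.node_X, self.node_U = self._std_rows(nf)
        self.node_t = nm["t"].to_numpy(float)
        self.node_subj = nm["subj"].to_numpy(int)
        self.node_w = nm["w"].to_numpy(float)
        self.node_female = nm["sex"].to_numpy(float) >= 0.5
        self.node_B = self.basis.evaluate(self.node_t)

        if death_rows:
            df = pd.DataFrame(
                death_rows,
                columns=["subj", "time", "fi", "sex", "treatment", "baseline_age"],
            )
            self.death_X, self.death_U = self._std_rows(df)
            self.death_t = df["time"].to_numpy(float)
            self.death_subj = df["subj"].to_numpy(int)
            self.death_female = df["sex"].to_numpy(float) >= 0.5
            self.death_B = self.basis.evaluate(self.death_t)
        else:
            self.death_subj = np.empty(0, int)

    def _layout(self):
        p = self.X.shape[1]
        m = self.n_basis - 1
        n = self.n_subjects
        sizes = {
            "beta_r": p, "beta_d": p, "log_sigma": 4, "y_corr": 6,
            "gamma": self.node_U.shape[1], "gamma_r": 1, "gamma_d": 1,
            "y_a_male": m, "y_a_female": m, "z": 4 * n,
        }
        self.slices = {}
        off = 0
        for k, s in sizes.items():
            self.slices[k] = slice(off, off + s)
            off += s
        self.dim = off

    def _unpack(self, theta):
        s = self.slices
        return {k: theta[v] for k, v in s.items()}

    # --------------------------------------------------------- log posterior

    def _logp_and_grad(self, theta):
        s = self.slices
        pr = self.priors
        p = self.X.shape[1]
        n = self.n_subjects
        g = np.zeros_like(theta)

        bR = theta[s["beta_r"]]
        bD = theta[s["beta_d"]]
        lsig = theta[s["log_sigma"]]
        ycor = theta[s["y_corr"]]
        gam = theta[s["gamma"]]
        gr = theta[s["gamma_r"]][0]
        gd = theta[s["gamma_d"]][0]
        yam = theta[s["y_a_male"]]
        yaf = theta[s["y_a_female"]]
        z = theta[s["z"]].reshape(n, 4)

        sig = np.exp(lsig)
        Lc = corr_cholesky(ycor, 4)
        Lz = z @ Lc.T
        b = Lz * sig  # (n, 4): b0_r, b1_r, b0_d, b1_d

        ll = 0.0
        G_b = np.zeros((n, 4))
        g_bR = np.zeros(p)
        g_bD = np.zeros(p)

        # ---- longitudinal Poisson terms
        XbR = self.X @ bR
        XbD = self.X @ bD
        eta_r = XbR + b[self.subj, 0] + b[self.subj, 1] * self.t_raw
        eta_d = XbD + b[self.subj, 2] + b[self.subj, 3] * self.t_raw
        for (eta, y, avail, mask, cols) in (
            (eta_r, self.y_r, self.n_row, self.rep_mask, (0, 1)),
            (eta_d, self.y_d, self.N - self.n_row, self.dam_mask, (2, 3)),
        ):
            lam = softplus(eta)
            mu = avail * lam * self.dt
            mpos = mask & (mu > 0)
            ll += np.sum(y[mpos] * np.log(mu[mpos]) - mu[mpos] - gammaln(y[mpos] + 1))
            d_eta = np.zeros_like(eta)
            d_eta[mpos] = (y[mpos] / lam[mpos] - avail[mpos] * self.dt[mpos]) \
                * softplus_derivative(eta[mpos])
            gX = self.X.T @ d_eta
            if cols[0] == 0:
                g_bR += gX
            else:
                g_bD += gX
            G_b[:, cols[0]] += np.bincount(self.subj, weights=d_eta, minlength=n)
            G_b[:, cols[1]] += np.bincount(self.subj, weights=d_eta * self.t_raw, minlength=n)

        # ---- survival terms
        a_m, logJ_m = stick_breaking(yam)
        a_f, logJ_f = stick_breaking(yaf)
        ll += logJ_m + logJ_f  # flat Dirichlet(1) prior: Jacobian only
        if not self.include_survival:
            # Poisson-only variant: survival parameters sampled from their
            # priors, longitudinal posterior untouched by the hazard
            g_gam = np.zeros(gam.size)
            g_gr = 0.0
            g_gd = 0.0
            g_am = np.zeros_like(a_m)
            g_af = np.zeros_like(a_f)
            return self._finish_logp(
                theta, g, ll, p, n, bR, bD, gam, gr, gd, yam, yaf, z, sig,
                Lc, Lz, G_b, g_bR, g_bD, g_gam, g_gr, g_gd, g_am, g_af,
            )

        h0_node = np.where(self.node_female, self.node_B @ a_f, self.node_B @ a_m)
        eta_r_nd = self.node_X @ bR + b[self.node_subj, 0] + b[self.node_subj, 1] * self.node_t
        eta_d_nd = self.node_X @ bD + b[self.node_subj, 2] + b[self.node_subj, 3] * self.node_t
        log_ex = self.node_U @ gam + gr * eta_r_nd + gd * eta_d_nd
        e = self.node_w * h0_node * np.exp(np.clip(log_ex, -700, 700))
        ll -= e.sum()

        g_gam = -(self.node_U.T @ e)
        g_gr = -np.sum(e * eta_r_nd)
        g_gd = -np.sum(e * eta_d_nd)
        d_eta_r_nd = -e * gr
        d_eta_d_nd = -e * gd
        g_bR += self.node_X.T @ d_eta_r_nd
        g_bD += self.node_X.T @ d_eta_d_nd
        G_b[:, 0] += np.bincount(self.node_subj, weights=d_eta_r_nd, minlength=n)
        G_b[:, 1] += np.bincount(self.node_subj, weights=d_eta_r_nd * self.node_t, minlength=n)
        G_b[:, 2] += np.bincount(self.node_subj, weights=d_eta_d_nd, minlength=n)
        G_b[:, 3] += np.bincount(self.node_subj, weights=d_eta_d_nd * self.node_t, minlength=n)
        ratio = e / np.maximum(h0_node, 1e-300)
        g_am = -(self.node_B[~self.node_female].T @ ratio[~self.node_female])
        g_af = -(self.node_B[self.node_female].T @ ratio[self.node_female])

        if self.death_subj.size:
            h0_d = np.where(self.death_female, self.death_B @ a_f, self.death_B @ a_m)
            h0_d = np.maximum(h0_d, 1e-300)
            eta_r_de = self.death_X @ bR + b[self.death_subj, 0] + b[self.death_subj, 1] * self.death_t
            eta_d_de = self.death_X @ bD + b[self.death_subj, 2] + b[self.death_subj, 3] * self.death_t
            ll += np.sum(np.log(h0_d)) + np.sum(self.death_U @ gam) \
                + gr * eta_r_de.sum() + gd * eta_d_de.sum()
            g_gam += self.death_U.sum(axis=0)
            g_gr += eta_r_de.sum()
            g_gd += eta_d_de.sum()
            g_bR += gr * self.death_X.sum(axis=0)
            g_bD += gd * self.death_X.sum(axis=0)
            G_b[:, 0] += gr * np.bincount(self.death_subj, minlength=n)
            G_b[:, 1] += gr * np.bincount(self.death_subj, weights=self.death_t, minlength=n)
            G_b[:, 2] += gd * np.bincount(self.death_subj, minlength=n)
            G_b[:, 3] += gd * np.bincount(self.death_subj, weights=self.death_t, minlength=n)
            inv = 1.0 / h0_d
            g_am += self.death_B[~self.death_female].T @ inv[~self.death_female]
            g_af += self.death_B[self.death_female].T @ inv[self.death_female]

        return self._finish_logp(
            theta, g, ll, p, n, bR, bD, gam, gr, gd, yam, yaf, z, sig,
            Lc, Lz, G_b, g_bR, g_bD, g_gam, g_gr, g_gd, g_am, g_af,
        )

    def _finish_logp(self, theta, g, ll, p, n, bR, bD, gam, gr, gd, yam, yaf,
                     z, sig, Lc, Lz, G_b, g_bR, g_bD, g_gam, g_gr, g_gd,
                     g_am, g_af):
        pr = self.priors
        s = self.slices
        lsig = theta[s["log_sigma"]]
        ycor = theta[s["y_corr"]]
        # ---- priors on fixed effects
        for (vec, gg) in ((bR, g_bR), (bD, g_bD)):
            sc = np.full(p, pr.coef_scale)
            sc[0] = pr.intercept_scale
            ll += -0.5 * np.sum((vec / sc) ** 2)
            gg -= vec / sc ** 2
        scu = np.full(gam.size, pr.coef_scale)
        scu[0] = pr.intercept_scale
        ll += -0.5 * np.sum((gam / scu) ** 2)
        g_gam -= gam / scu ** 2
        ll += -0.5 * (gr ** 2 + gd ** 2)
        g_gr -= gr
        g_gd -= gd

        # ---- random-effect block
        ll += -0.5 * np.sum(z * z)
        g_z = ((G_b * sig) @ Lc) - z
        lp_sig, g_lsig_prior = log_halfcauchy(lsig, pr.re_sd_scale)
        ll += lp_sig.sum()
        g_lsig = np.sum(G_b * Lz, axis=0) * sig + g_lsig_prior
        G_L = (G_b * sig).T @ z
        lp_corr, g_ycor_prior = corr_logprior_and_grad(ycor, 4, pr.lkj_eta)
        ll += lp_corr
        g_ycor = corr_chol_grad_y(ycor, 4, G_L) + g_ycor_prior

        # ---- spline simplex VJPs (adds stick-breaking Jacobian gradient)
        _, _, g_yam = stick_breaking_vjp(yam, g_am)
        _, _, g_yaf = stick_breaking_vjp(yaf, g_af)

        g[self.slices["beta_r"]] = g_bR
        g[self.slices["beta_d"]] = g_bD
        g[self.slices["log_sigma"]] = g_lsig
        g[self.slices["y_corr"]] = g_ycor
        g[self.slices["gamma"]] = g_gam
        g[self.slices["gamma_r"]] = g_gr
        g[self.slices["gamma_d"]] = g_gd
        g[self.slices["y_a_male"]] = g_yam
        g[self.slices["y_a_female"]] = g_yaf
        g[self.slices["z"]] = g_z.reshape(-1)
        return float(ll), g

    # ----------------------------------------------------------------- fit

    def _initial_point(self):
        theta = np.zeros(self.dim)
        crude_r = max(self.y_r.sum() / max(np.sum(self.n_row * self.dt), 1e-9), 1e-3)
        crude_d = max(
            self.y_d.sum() / max(np.sum((self.N - self.n_row) * self.dt), 1e-9), 1e-3
        )
        theta[self.slices["beta_r"].start] = softplus_inverse(crude_r)
        theta[self.slices["beta_d"].start] = softplus_inverse(crude_d)
        theta[self.slices["log_sigma"]] = np.log(0.1)
        return theta

    def fit(self, n_warmup=400, n_samples=400, n_chains=2, seed=0,
            max_leapfrog=24, target_accept=0.85, rhat_limit=1.05,
            on_bad_convergence="raise") -> "MouseJointResults":
        """Sample the joint posterior; fails loudly on R-hat > ``rhat_limit``.

        ``on_bad_convergence``: "raise" (default) or "warn".
        """
        res = run_hmc(
            self._logp_and_grad, self._initial_point(),
            n_warmup=n_warmup, n_samples=n_samples, n_chains=n_chains,
            seed=seed, max_leapfrog=max_leapfrog, target_accept=target_accept,
        )
        post = self._to_posterior(res.draws)
        results = MouseJointResults(self, post, res)
        bad = results.check_convergence(rhat_limit)
        if bad:
            msg = f"split-R-hat > {rhat_limit} for fixed effects: {bad}"
            if on_bad_convergence == "raise":
                raise ConvergenceError(msg)
            warnings.warn(msg, stacklevel=2)
        return results

    def _to_posterior(self, raw) -> PosteriorDraws:
        nc, nd, _ = raw.shape
        s = self.slices
        n = self.n_subjects
        nb = self.n_basis
        out = {
            "beta_r": raw[:, :, s["beta_r"]],
            "beta_d": raw[:, :, s["beta_d"]],
            "gamma": raw[:, :, s["gamma"]],
            "gamma_r": raw[:, :, s["gamma_r"]][:, :, 0],
            "gamma_d": raw[:, :, s["gamma_d"]][:, :, 0],
            "sigma": np.exp(raw[:, :, s["log_sigma"]]),
        }
        Om = np.empty((nc, nd, 4, 4))
        am = np.empty((nc, nd, nb))
        af = np.empty((nc, nd, nb))
        b = np.empty((nc, nd, n, 4))
        for c in range(nc):
            for d_ in range(nd):
                Lc = corr_cholesky(raw[c, d_, s["y_corr"]], 4)
                Om[c, d_] = Lc @ Lc.T
                am[c, d_], _ = stick_breaking(raw[c, d_, s["y_a_male"]])
                af[c, d_], _ = stick_breaking(raw[c, d_, s["y_a_female"]])
                sigv = np.exp(raw[c, d_, s["log_sigma"]])
                zv = raw[c, d_, s["z"]].reshape(n, 4)
                b[c, d_] = (zv @ Lc.T) * sigv
        out.update(Omega=Om, a_male=am, a_female=af, b=b)
        return PosteriorDraws(out)


class MouseJointResults:
    """Posterior draws plus the design needed to form derived quantities."""

    def __init__(self, model: MouseJointModel, posterior: PosteriorDraws, sampler):
        self.model = model
        self.posterior = posterior
        self.sampler = sampler

    def summary(self, diagnostics: bool = True) -> pd.DataFrame:
        return self.posterior.summary(
            names=FIXED_EFFECT_NAMES + ["sigma", "Omega"], diagnostics=diagnostics
        )

    def check_convergence(self, rhat_limit=1.05):
        tab = self.posterior.summary(names=FIXED_EFFECT_NAMES, diagnostics=True)
        bad = tab.loc[tab["rhat"] > rhat_limit, "parameter"].tolist()
        return bad

    # ------------------------------------------------------- linear predictors

    def eta_draws(self, t, sex, treatment, f, a0, process="repair",
                  random_effects=None):
        """Per-draw link-scale rate at covariate values (population profile).

        ``random_effects``: optional (intercept, slope) arrays per draw; by
        default the population profile (random effects at zero).
        """
        frame = pd.DataFrame({
            "time": np.atleast_1d(np.asarray(t, float)),
            "sex": sex, "treatment": treatment, "fi": f, "baseline_age": a0,
        })
        X, _ = self.model._std_rows(frame)
        name = "beta_r" if process == "repair" else "beta_d"
        beta = self.posterior.flat(name)  # (S, p)
        eta = beta @ X.T  # (S, T)
        if random_effects is not None:
            b0, b1 = random_effects
            eta = eta + b0[:, None] + b1[:, None] * np.atleast_1d(t)[None, :]
        return eta

    def rate_draws(self, t, sex, treatment, f, a0, process="repair", **kw):
        return softplus(self.eta_draws(t, sex, treatment, f, a0, process, **kw))

    def linear_predictor_draws(self, process="repair", max_draws=None,
                               resample_random_effects=False, rng=None):
        """Per-draw eta at the fitted subject-interval rows, shape (S, n_rows).

        With ``resample_random_effects`` the subject effects are re-drawn
        from their population distribution per draw (mixed replication)
        instead of using each subject's fitted values (conditional).
        """
        m = self.model
        name = "beta_r" if process == "repair" else "beta_d"
        beta = self.posterior.flat(name)
        b = self.posterior.flat("b")
        if max_draws is not None and beta.shape[0] > max_draws:
            step = beta.shape[0] // max_draws
            beta, b = beta[::step][:max_draws], b[::step][:max_draws]
        if resample_random_effects:
            rng = rng or np.random.default_rng(0)
            sig = self.posterior.flat("sigma")
            Om = self.posterior.flat("Omega")
            if max_draws is not None and sig.shape[0] > b.shape[0]:
                step = sig.shape[0] // b.shape[0]
                sig, Om = sig[::step][: b.shape[0]], Om[::step][: b.shape[0]]
            S = b.shape[0]
            b = np.empty_like(b)
            for s_i in range(S):
                L = np.linalg.cholesky(
                    np.diag(sig[s_i]) @ Om[s_i] @ np.diag(sig[s_i])
                    + 1e-12 * np.eye(4)
                )
                b[s_i] = rng.standard_normal((m.n_subjects, 4)) @ L.T
        c0, c1 = (0, 1) if process == "repair" else (2, 3)
        return beta @ m.X.T + b[:, m.subj, c0] + b[:, m.subj, c1] * m.t_raw[None, :]

    # ------------------------------------------------------------- survival

    def survival_draws(self, subject_id, t_grid):
        """Per-draw S(t) for one fitted subject on a time grid."""
        m = self.model
        si = int(np.where(m.design.subject_ids == subject_id)[0][0])
        sel = m.node_subj == si
        nodes_t = m.node_t[sel]
        nodes_w = m.node_w[sel]
        X = m.node_X[sel]
        U = m.node_U[sel]
        B = m.node_B[sel]
        female = bool(m.node_female[sel][0]) if sel.any() else False
        post = self.posterior
        bR = post.flat("beta_r")
        bD = post.flat("beta_d")
        gam = post.flat("gamma")
        gr = post.flat("gamma_r")
        gd = post.flat("gamma_d")
        a = post.flat("a_female" if female else "a_male")
        b = post.flat("b")[:, si, :]  # (S, 4)
        eta_r = bR @ X.T + b[:, [0]] + b[:, [1]] * nodes_t[None, :]
        eta_d = bD @ X.T + b[:, [2]] + b[:, [3]] * nodes_t[None, :]
        h0 = a @ B.T
        h = h0 * np.exp(gam @ U.T + gr[:, None] * eta_r + gd[:, None] * eta_d)
        t_grid = np.asarray(t_grid, float)
        S = np.empty((h.shape[0], t_grid.size))
        for j, t in enumerate(t_grid):
            w = np.where(nodes_t <= t, nodes_w, 0.0)
            S[:, j] = np.exp(-(h * w[None, :]).sum(axis=1))
        return S


def expected_fixed_effects(truth, model: MouseJointModel) -> dict:
    """Map generating (raw-design) coefficients onto the fitted design basis.

    Returns the coefficient values the fit should recover for ``beta_r``,
    ``beta_d``, ``gamma`` (on the standardized design) and the invariant
    loadings ``gamma_r``, ``gamma_d``.
    """
    d = model.counts.data
    fi = d["n"].to_numpy(float) / model.N
    dt = d["dt"].to_numpy(float)
    X_raw = mouse_raw_design(
        d["time"], d["sex"], d["treatment"], fi, d["baseline_age"]
    )
    U_raw = mouse_raw_survival_design(d["sex"], d["treatment"], fi, d["baseline_age"])

    def _effective_eta(beta):
        # The generator transitions items with the exact exponential-interval
        # probability, so the Poisson fit's estimand is the discretized
        # effective rate (1 - exp(-lambda dt)) / dt, not lambda itself;
        # project that (population profile, random effects at zero) onto the
        # fitted design.
        lam = softplus(X_raw @ beta)
        lam_eff = -np.expm1(-lam * dt) / dt
        eta_eff = softplus_inverse(np.maximum(lam_eff, 1e-12))
        b, *_ = np.linalg.lstsq(model.X, eta_eff, rcond=None)
        return b

    # The fitted baseline-hazard shape integrates to 1 over the knot span,
    # whereas the generating piecewise-constant baseline carries a free
    # per-sex scale; that scale is absorbed by the fitted survival
    # intercept/sex coefficients.
    def _pc_integral(vals):
        edges = truth.base_hazard_edges
        lo, hi = model.knots[0], model.knots[-1]
        grid = np.unique(np.concatenate(([lo, hi], edges[(edges > lo) & (edges < hi)])))
        total = 0.0
        for a, b in zip(grid[:-1], grid[1:]):
            i = np.clip(np.searchsorted(edges, 0.5 * (a + b), side="right") - 1,
                        0, len(vals) - 1)
            total += vals[i] * (b - a)
        return total

    log_c_m = np.log(_pc_integral(truth.base_hazard_male))
    log_c_f = np.log(_pc_integral(truth.base_hazard_female))
    sex = d["sex"].to_numpy(float)
    eta_u = U_raw @ truth.gamma + log_c_m + sex * (log_c_f - log_c_m)
    gamma_to, *_ = np.linalg.lstsq(model.design.U, eta_u, rcond=None)
    return {
        "beta_r": _effective_eta(truth.beta_r),
        "beta_d": _effective_eta(truth.beta_d),
        "gamma": gamma_to,
        "gamma_r": truth.gamma_r,
        "gamma_d": truth.gamma_d,
    }
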