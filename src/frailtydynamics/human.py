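"""Non-linear varying-coefficient Poisson model for human damage/repair rates.

For large human cohorts (ELSA-style), linear age/wealth effects are not
enough: the base rate, its sex offset and its time-slope are allowed to
vary smoothly over (wealth, baseline age) through tensor-product order-3
B-spline surfaces with 2D random-walk smoothing priors. Per process,

``eta_i(t) = s1(w, a0) + s2(w, a0) sex + s3(w, a0) t_z + s4(w, a0) sex t_z
+ beta . (f, sex f, w f, a0 f) + b_i``

with subject random intercepts only (no random slopes: human follow-up
series are short and slopes overfit, inflating residual credible-interval
coverage toward 1). Global intercept/sex/time/wealth/age fixed effects are
not sampled separately: they lie exactly in the span of the four surfaces
and their multipliers, and sampling them as well would leave the posterior
degenerate along prior-only ridges; only the FI (frailty-feedback) terms
need a separate fixed-effect block. Rates come through the Softplus link and enter the
same interval-start Poisson count likelihood as the mouse model. There is
no survival component (no mortality data for the wealth-linked cohort).

Each 5x5 coefficient grid ``s_ij`` gets its own smoothing prior: the corner
is N(0,1), edge cells follow a one-sided random walk along their only
available predecessor, and interior cells follow the two-component density
mixture ``p_w N(s[i-1,j], tau_w) + p_a N(s[i,j-1], tau_a)`` with
``(p_w, p_a) ~ Dirichlet(1.5)`` and half-normal(0,1) step scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .design import Standardizer
from .links import softplus, softplus_derivative, softplus_inverse
from .mcmc import ConvergenceError, run_hmc
from .posterior import PosteriorDraws
from .splines import bspline_basis_1d, make_knots_surface, tensor_surface_design
from .transforms import (
    corr_cholesky,
    corr_chol_grad_y,
    corr_logprior_and_grad,
    log_halfcauchy,
    log_halfnormal,
)
from .transitions import TransitionCounts

__all__ = [
    "SmoothingPrior",
    "HumanSplineModel",
    "HumanSplineResults",
    "bspline_surface",
    "random_walk_logprior",
]

HUMAN_FIXED = ["beta_r", "beta_d"]
SURFACE_NAMES = ["base", "sex", "t", "sex_t"]

_SQRT_2PI = np.sqrt(2.0 * np.pi)


def bspline_surface(w, a0, coefficients, knots_w, knots_a0):
    """Evaluate a tensor-product order-3 B-spline surface at (w, a0) points."""
    coefficients = np.asarray(coefficients, dtype=float)
    T = tensor_surface_design(np.atleast_1d(w), np.atleast_1d(a0), knots_w, knots_a0)
    return T @ coefficients.reshape(-1)


@dataclass
class SmoothingPrior:
    """Hyperparameters of the 2D random-walk smoothing prior for one surface."""

    tau_w: float
    tau_a0: float
    p_w: float

    def __post_init__(self):
        if self.tau_w <= 0 or self.tau_a0 <= 0:
            raise ValueError("random-walk step scales must be positive")
        if not 0 < self.p_w < 1:
            raise ValueError("direction weight p_w must lie in (0, 1)")

    @property
    def p_a0(self):
        return 1.0 - self.p_w


def _norm_pdf(x, mu, tau):
    return np.exp(-0.5 * ((x - mu) / tau) ** 2) / (tau * _SQRT_2PI)


def random_walk_logprior(s, prior: SmoothingPrior) -> float:
    """Log-density of a coefficient grid under the 2D random-walk prior.

    Corner cell N(0,1); first row/column one-sided walks; interior cells the
    two-direction density mixture.
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 2:
        raise ValueError("coefficient grid must be 2D")
    lp = -0.5 * s[0, 0] ** 2 - 0.5 * np.log(2 * np.pi)
    # first column: walk along wealth axis; first row: along age axis
    for i in range(1, s.shape[0]):
        lp += np.log(_norm_pdf(s[i, 0], s[i - 1, 0], prior.tau_w))
    for j in range(1, s.shape[1]):
        lp += np.log(_norm_pdf(s[0, j], s[0, j - 1], prior.tau_a0))
    for i in range(1, s.shape[0]):
        for j in range(1, s.shape[1]):
            m = prior.p_w * _norm_pdf(s[i, j], s[i - 1, j], prior.tau_w) \
                + prior.p_a0 * _norm_pdf(s[i, j], s[i, j - 1], prior.tau_a0)
            lp += np.log(m)
    return float(lp)


class HumanSplineModel:
    """Varying-coefficient damage/repair model built from transition counts.

    ``counts.data`` must carry ``sex``, ``wealth`` and ``baseline_age``
    covariates (wealth already log-transformed by preprocessing).
    """

    def __init__(self, counts: TransitionCounts, priors=None,
                 knots_w=None, knots_a0=None):
        counts.validate()
        self.counts = counts
        self.N = counts.n_items
        d = counts.data
        for col in ("sex", "wealth", "baseline_age"):
            if col not in d.columns:
                raise ValueError(f"human model requires covariate {col!r}")
        ids, sidx = np.unique(d["subject_id"].to_numpy(), return_inverse=True)
        self.subject_ids = ids
        self.subj = sidx
        self.n_subjects = len(ids)

        dd = d.copy()
        dd["fi"] = dd["n"] / self.N
        base = ["time", "sex", "wealth", "fi", "baseline_age"]
        self.standardizer = Standardizer.fit(dd, base)
        z = {c: self.standardizer.transform(dd, c) for c in base}
        one = np.ones(len(dd))
        # Identified fixed-effect block: only the FI terms. The remaining
        # global covariate structure (intercept, t, sex, w, a0 and their
        # t-interactions) is exactly spanned by the four varying-coefficient
        # surfaces and their multipliers, so sampling it separately would
        # leave the posterior degenerate along prior-only ridges.
        self.X = np.column_stack([
            z["fi"], z["sex"] * z["fi"], z["wealth"] * z["fi"],
            z["baseline_age"] * z["fi"],
        ])
        self.x_names = ["fi", "sex:fi", "wealth:fi", "baseline_age:fi"]
        self.p = self.X.shape[1]

        w_subj = dd.groupby("subject_id", sort=True)["wealth"].first()
        a_subj = dd.groupby("subject_id", sort=True)["baseline_age"].first()
        self.knots_w = np.asarray(knots_w, float) if knots_w is not None \
            else make_knots_surface(w_subj.to_numpy())
        self.knots_a0 = np.asarray(knots_a0, float) if knots_a0 is not None \
            else make_knots_surface(a_subj.to_numpy())
        self.nb_w = bspline_basis_1d(self.knots_w[:1], self.knots_w).shape[1]
        self.nb_a = bspline_basis_1d(self.knots_a0[:1], self.knots_a0).shape[1]
        self.n_cells = self.nb_w * self.nb_a
        # per-row tensor basis (constant within subject)
        self.Trow = tensor_surface_design(
            dd["wealth"].to_numpy(float), dd["baseline_age"].to_numpy(float),
            self.knots_w, self.knots_a0,
        )
        # surface multipliers: 1, sex, t_z, sex * t_z (sex as raw indicator)
        sex_raw = dd["sex"].to_numpy(float)
        self.mult = np.column_stack([one, sex_raw, z["time"], sex_raw * z["time"]])

        self.n_row = dd["n"].to_numpy(float)
        self.dt = dd["dt"].to_numpy(float)
        self.y_r = dd["n_repair"].to_numpy(float)
        self.y_d = dd["n_damage"].to_numpy(float)
        self.rep_mask = self.n_row > 0
        self.dam_mask = self.n_row < self.N
        self.intercept_scale = 3.0
        self.coef_scale = 1.0
        self.tau_floor = 0.05
        self._layout()

    def _layout(self):
        n = self.n_subjects
        nc = self.n_cells
        sizes = {
            "beta_r": self.p, "beta_d": self.p,
            "s": 8 * nc,            # 2 processes x 4 surfaces
            "log_tau": 16,          # (tau_w, tau_a0) per surface
            "logit_pw": 8,
            "log_sigma": 2, "y_corr": 1,
            "z": 2 * n,
        }
        self.slices = {}
        off = 0
        for k, v in sizes.items():
            self.slices[k] = slice(off, off + v)
            off += v
        self.dim = off

    # --------------------------------------------------- random-walk prior

    def _rw_logp_grad(self, S, tau_w, tau_a, pw):
        """Vectorized over the 8 surfaces: S (8, nw, na), tau/p (8,).

        Returns (logp, dS, dlogp/dtau_w, dlogp/dtau_a, dlogit_pw); the
        caller applies the tau parameterization chain rule and hyperpriors.
        """
        nw, na = self.nb_w, self.nb_a
        lp = 0.0
        dS = np.zeros_like(S)
        dltw = np.zeros(8)
        dlta = np.zeros(8)
        dlpw = np.zeros(8)

        c = S[:, 0, 0]
        lp += np.sum(-0.5 * c ** 2 - 0.5 * np.log(2 * np.pi))
        dS[:, 0, 0] -= c

        def one_sided(cur, prev, tau, which):
            r = (cur - prev) / tau[:, None]
            lp_loc = -0.5 * r ** 2 - np.log(tau[:, None] * _SQRT_2PI)
            d_cur = -r / tau[:, None]
            d_tau = (r ** 2 - 1.0) / tau[:, None]  # d/d tau
            return lp_loc.sum(), d_cur, d_tau.sum(axis=1), which

        # first column (walk in wealth direction)
        if nw > 1:
            cur, prev = S[:, 1:, 0], S[:, :-1, 0]
            l, d_cur, d_tau, _ = one_sided(cur, prev, tau_w, "w")
            lp += l
            dS[:, 1:, 0] += d_cur
            dS[:, :-1, 0] -= d_cur
            dltw += d_tau
        if na > 1:
            cur, prev = S[:, 0, 1:], S[:, 0, :-1]
            l, d_cur, d_tau, _ = one_sided(cur, prev, tau_a, "a")
            lp += l
            dS[:, 0, 1:] += d_cur
            dS[:, 0, :-1] -= d_cur
            dlta += d_tau

        if nw > 1 and na > 1:
            cur = S[:, 1:, 1:]
            pw_ = pw[:, None, None]
            tw = tau_w[:, None, None]
            ta = tau_a[:, None, None]
            rw = (cur - S[:, :-1, 1:]) / tw
            ra = (cur - S[:, 1:, :-1]) / ta
            Nw = np.exp(-0.5 * rw ** 2) / (tw * _SQRT_2PI)
            Na = np.exp(-0.5 * ra ** 2) / (ta * _SQRT_2PI)
            m = pw_ * Nw + (1 - pw_) * Na
            lp += np.sum(np.log(m))
            wNw = pw_ * Nw / m
            wNa = (1 - pw_) * Na / m
            d_cur = -wNw * rw / tw - wNa * ra / ta
            dS[:, 1:, 1:] += d_cur
            dS[:, :-1, 1:] += wNw * rw / tw
            dS[:, 1:, :-1] += wNa * ra / ta
            dltw += np.sum(wNw * (rw ** 2 - 1.0), axis=(1, 2)) / tau_w
            dlta += np.sum(wNa * (ra ** 2 - 1.0), axis=(1, 2)) / tau_a
            dlpw += np.sum((Nw - Na) / m, axis=(1, 2)) * pw * (1 - pw)

        # hyperprior on the direction weights: p_w ~ Beta(1.5, 1.5) (+Jacobian)
        lp += np.sum(1.5 * np.log(pw) + 1.5 * np.log1p(-pw))
        dlpw += 1.5 * (1 - pw) - 1.5 * pw  # incl. logit Jacobian d log(p(1-p))/du
        return lp, dS, dltw, dlta, dlpw

    # --------------------------------------------------------- log posterior

    def _logp_and_grad(self, theta):
        s = self.slices
        n = self.n_subjects
        g = np.zeros_like(theta)

        bR = theta[s["beta_r"]]
        bD = theta[s["beta_d"]]
        S = theta[s["s"]].reshape(8, self.nb_w, self.nb_a)
        ltau = theta[s["log_tau"]].reshape(8, 2)
        lpw = theta[s["logit_pw"]]
        lsig = theta[s["log_sigma"]]
        ycor = theta[s["y_corr"]]
        z = theta[s["z"]].reshape(n, 2)

        # small floor on the walk scales caps the funnel when the posterior
        # prefers perfectly flat surfaces (tau -> 0); below it the prior is
        # effectively flat in log tau
        tau_w = self.tau_floor + np.exp(ltau[:, 0])
        tau_a = self.tau_floor + np.exp(ltau[:, 1])
        pw = expit(lpw)
        sig = np.exp(lsig)
        Lc = corr_cholesky(ycor, 2)
        Lz = z @ Lc.T
        b = Lz * sig

        ll = 0.0
        g_bR = np.zeros(self.p)
        g_bD = np.zeros(self.p)
        G_b = np.zeros((n, 2))
        gS = np.zeros_like(S)

        Sflat = S.reshape(8, -1)
        surf_vals = self.Trow @ Sflat.T  # (M, 8)
        surf_r = np.sum(self.mult * surf_vals[:, :4], axis=1)
        surf_d = np.sum(self.mult * surf_vals[:, 4:], axis=1)
        eta_r = self.X @ bR + surf_r + b[self.subj, 0]
        eta_d = self.X @ bD + surf_d + b[self.subj, 1]

        for (eta, y, avail, mask, proc) in (
            (eta_r, self.y_r, self.n_row, self.rep_mask, 0),
            (eta_d, self.y_d, self.N - self.n_row, self.dam_mask, 1),
        ):
            lam = softplus(eta)
            mu = avail * lam * self.dt
            mpos = mask & (mu > 0)
            ll += np.sum(y[mpos] * np.log(mu[mpos]) - mu[mpos] - gammaln(y[mpos] + 1))
            d_eta = np.zeros_like(eta)
            d_eta[mpos] = (y[mpos] / lam[mpos] - avail[mpos] * self.dt[mpos]) \
                * softplus_derivative(eta[mpos])
            if proc == 0:
                g_bR += self.X.T @ d_eta
            else:
                g_bD += self.X.T @ d_eta
            G_b[:, proc] += np.bincount(self.subj, weights=d_eta, minlength=n)
            block = slice(0, 4) if proc == 0 else slice(4, 8)
            # d eta / d s_k = mult[:, k] * Trow
            gS[block] += np.einsum(
                "m,mk,mc->kc", d_eta, self.mult, self.Trow
            ).reshape(4, self.nb_w, self.nb_a)

        # fixed-effect priors (no intercept column; the base surface's
        # corner cell plays that role)
        for vec, gg in ((bR, g_bR), (bD, g_bD)):
            ll += -0.5 * np.sum((vec / self.coef_scale) ** 2)
            gg -= vec / self.coef_scale ** 2

        # smoothing priors
        lp_rw, dS, dtw, dta, dlpw = self._rw_logp_grad(S, tau_w, tau_a, pw)
        ll += lp_rw
        gS += dS
        # tau = floor + exp(ltau): half-normal(0,1) prior on tau with the
        # exp-part Jacobian
        ll += np.sum(0.5 * np.log(2.0 / np.pi) - 0.5 * tau_w ** 2 + ltau[:, 0])
        ll += np.sum(0.5 * np.log(2.0 / np.pi) - 0.5 * tau_a ** 2 + ltau[:, 1])
        dltw = (dtw - tau_w) * (tau_w - self.tau_floor) + 1.0
        dlta = (dta - tau_a) * (tau_a - self.tau_floor) + 1.0

        # random intercepts
        ll += -0.5 * np.sum(z * z)
        g_z = ((G_b * sig) @ Lc) - z
        lp_sig, g_lsig_prior = log_halfcauchy(lsig, 1.0)
        ll += lp_sig.sum()
        g_lsig = np.sum(G_b * Lz, axis=0) * sig + g_lsig_prior
        G_L = (G_b * sig).T @ z
        lp_corr, g_ycor_prior = corr_logprior_and_grad(ycor, 2, 2.0)
        ll += lp_corr
        g_ycor = corr_chol_grad_y(ycor, 2, G_L) + g_ycor_prior

        g[s["beta_r"]] = g_bR
        g[s["beta_d"]] = g_bD
        g[s["s"]] = gS.reshape(-1)
        g[s["log_tau"]] = np.column_stack([dltw, dlta]).reshape(-1)
        g[s["logit_pw"]] = dlpw
        g[s["log_sigma"]] = g_lsig
        g[s["y_corr"]] = g_ycor
        g[s["z"]] = g_z.reshape(-1)
        return float(ll), g

    # ----------------------------------------------------------------- fit

    def _initial_point(self):
        theta = np.zeros(self.dim)
        crude_r = max(self.y_r.sum() / max(np.sum(self.n_row * self.dt), 1e-9), 1e-3)
        crude_d = max(
            self.y_d.sum() / max(np.sum((self.N - self.n_row) * self.dt), 1e-9),
            1e-3,
        )
        # the base surfaces carry the intercepts: start them flat at the
        # crude pooled link-scale rates
        nc = self.n_cells
        S0 = theta[self.slices["s"]].reshape(8, nc)
        S0[0, :] = softplus_inverse(crude_r)
        S0[4, :] = softplus_inverse(crude_d)
        theta[self.slices["s"]] = S0.reshape(-1)
        theta[self.slices["log_sigma"]] = np.log(0.1)
        theta[self.slices["log_tau"]] = np.log(0.5)
        return theta

    def fit(self, n_warmup=800, n_samples=800, n_chains=2, seed=0,
            max_leapfrog=48, target_accept=0.9, rhat_limit=1.05,
            on_bad_convergence="raise") -> "HumanSplineResults":
        res = run_hmc(
            self._logp_and_grad, self._initial_point(),
            n_warmup=n_warmup, n_samples=n_samples, n_chains=n_chains,
            seed=seed, max_leapfrog=max_leapfrog, target_accept=target_accept,
        )
        post = self._to_posterior(res.draws)
        results = HumanSplineResults(self, post, res)
        bad = results.check_convergence(rhat_limit)
        if bad:
            msg = f"split-R-hat > {rhat_limit} for fixed effects: {bad}"
            if on_bad_convergence == "raise":
                raise ConvergenceError(msg)
            warnings.warn(msg, stacklevel=2)
        return results

    def _to_posterior(self, raw):
        nc, nd, _ = raw.shape
        s = self.slices
        n = self.n_subjects
        out = {
            "beta_r": raw[:, :, s["beta_r"]],
            "beta_d": raw[:, :, s["beta_d"]],
            "sigma": np.exp(raw[:, :, s["log_sigma"]]),
            "p_w": expit(raw[:, :, s["logit_pw"]]),
            "tau": np.exp(raw[:, :, s["log_tau"]]).reshape(nc, nd, 8, 2),
        }
        Sdraws = raw[:, :, s["s"]].reshape(nc, nd, 8, self.nb_w, self.nb_a)
        for k, name in enumerate(SURFACE_NAMES):
            out[f"surf_r_{name}"] = Sdraws[:, :, k]
            out[f"surf_d_{name}"] = Sdraws[:, :, 4 + k]
        Om = np.empty((nc, nd, 2, 2))
        b = np.empty((nc, nd, n, 2))
        for c in range(nc):
            for d_ in range(nd):
                Lc = corr_cholesky(raw[c, d_, s["y_corr"]], 2)
                Om[c, d_] = Lc @ Lc.T
                sigv = np.exp(raw[c, d_, s["log_sigma"]])
                b[c, d_] = (raw[c, d_, s["z"]].reshape(n, 2) @ Lc.T) * sigv
        out.update(Omega=Om, b=b)
        return PosteriorDraws(out)


class HumanSplineResults:
    def __init__(self, model: HumanSplineModel, posterior: PosteriorDraws, sampler):
        self.model = model
        self.posterior = posterior
        self.sampler = sampler

    def summary(self, diagnostics: bool = True) -> pd.DataFrame:
        return self.posterior.summary(
            names=HUMAN_FIXED + ["sigma", "Omega"], diagnostics=diagnostics
        )

    def check_convergence(self, rhat_limit=1.05):
        tab = self.posterior.summary(names=HUMAN_FIXED, diagnostics=True)
        return tab.loc[tab["rhat"] > rhat_limit, "parameter"].tolist()

    def surface_draws(self, process, which, w, a0):
        """Per-draw surface values: process 'repair'|'damage', which in
        {'base','sex','t','sex_t'}; returns (S, len(w)) for paired points."""
        key = f"surf_{'r' if process == 'repair' else 'd'}_{which}"
        S = self.posterior.flat(key)  # (S, nw, na)
        T = tensor_surface_design(
            np.atleast_1d(w), np.atleast_1d(a0),
            self.model.knots_w, self.model.knots_a0,
        )
        return S.reshape(S.shape[0], -1) @ T.T

    def eta_draws(self, t, sex, wealth, f, a0, process="repair"):
        """Per-draw link-scale rate at a covariate profile (random effects 0)."""
        m = self.model
        frame = pd.DataFrame({
            "time": np.atleast_1d(np.asarray(t, float)),
            "sex": sex, "wealth": wealth, "fi": f, "baseline_age": a0,
        })
        std = m.standardizer
        z = {c: std.transform(frame, c)
             for c in ["time", "sex", "wealth", "fi", "baseline_age"]}
        one = np.ones(len(frame))
        X = np.column_stack([
            z["fi"], z["sex"] * z["fi"], z["wealth"] * z["fi"],
            z["baseline_age"] * z["fi"],
        ])
        name = "beta_r" if process == "repair" else "beta_d"
        beta = self.posterior.flat(name)
        eta = beta @ X.T
        w_arr = frame["wealth"].to_numpy(float)
        a_arr = frame["baseline_age"].to_numpy(float)
        sex_raw = frame["sex"].to_numpy(float)
        mult = np.column_stack([one, sex_raw, z["time"], sex_raw * z["time"]])
        for k, which in enumerate(SURFACE_NAMES):
            sv = self.surface_draws(process, which, w_arr, a_arr)
            eta = eta + sv * mult[:, k][None, :]
        return eta

    def rate_draws(self, t, sex, wealth, f, a0, process="repair"):
        return softplus(self.eta_draws(t, sex, wealth, f, a0, process))

    def linear_predictor_draws(self, process="repair", max_draws=None,
                               resample_random_effects=False, rng=None):
        """Per-draw eta at the fitted rows (incl. surfaces and random
        intercepts), shape (S, n_rows); optionally with mixed-replication
        random intercepts (re-drawn from the population distribution)."""
        m = self.model
        name = "beta_r" if process == "repair" else "beta_d"
        beta = self.posterior.flat(name)
        b = self.posterior.flat("b")
        if resample_random_effects:
            rng = rng or np.random.default_rng(0)
            sig = self.posterior.flat("sigma")
            Om = self.posterior.flat("Omega")
            b = b.copy()
            for s_i in range(b.shape[0]):
                L = np.linalg.cholesky(
                    np.diag(sig[s_i]) @ Om[s_i] @ np.diag(sig[s_i])
                    + 1e-12 * np.eye(2)
                )
                b[s_i] = rng.standard_normal((m.n_subjects, 2)) @ L.T
        pref = "r" if process == "repair" else "d"
        surfs = [self.posterior.flat(f"surf_{pref}_{w}") for w in SURFACE_NAMES]
        if max_draws is not None and beta.shape[0] > max_draws:
            step = beta.shape[0] // max_draws
            sel = slice(None, None, step)
            beta = beta[sel][:max_draws]
            b = b[sel][:max_draws]
            surfs = [s[sel][:max_draws] for s in surfs]
        eta = beta @ m.X.T
        for k, S in enumerate(surfs):
            vals = S.reshape(S.shape[0], -1) @ m.Trow.T  # (S, M)
            eta = eta + vals * m.mult[:, k][None, :]
        proc = 0 if process == "repair" else 1
        return eta + b[:, m.subj, proc]
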