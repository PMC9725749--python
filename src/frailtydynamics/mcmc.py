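"""Hamiltonian Monte Carlo engine used by all Bayesian models in the package.

A plain HMC sampler with dual-averaging step-size adaptation toward a
target acceptance rate, diagonal mass-matrix adaptation during warmup, and
uniformly jittered leapfrog trajectory lengths (which avoids resonant
periodic trajectories without the bookkeeping of a dynamic-length sampler).
Models supply ``logp_and_grad(theta) -> (float, ndarray)`` with analytic
gradients; all parameters live in an unconstrained space (see
:mod:`frailtydynamics.transforms`).

Convergence is summarized with split-R-hat and bulk effective sample size
via ``arviz``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["run_hmc", "HMCDraws", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """Raised when chains fail the R-hat contract of a fit."""


@dataclass
class HMCDraws:
    """Raw sampler output: draws of shape (n_chains, n_samples, dim)."""

    draws: np.ndarray
    accept_rate: float
    step_size: float
    n_divergent: int

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])


def _leapfrog(logp_and_grad, theta, p, eps, n_steps, inv_mass, grad):
    p = p + 0.5 * eps * grad
    for s in range(n_steps):
        theta = theta + eps * inv_mass * p
        lp, grad = logp_and_grad(theta)
        if not np.isfinite(lp):
            return theta, p, lp, grad
        if s < n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return theta, p, lp, grad


def _find_initial_step(logp_and_grad, theta, inv_mass, rng):
    eps = 0.1
    lp0, grad0 = logp_and_grad(theta)
    p = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = lp0 - 0.5 * np.sum(inv_mass * p * p)
    _, p1, lp1, _ = _leapfrog(logp_and_grad, theta, p, eps, 1, inv_mass, grad0)
    h1 = lp1 - 0.5 * np.sum(inv_mass * p1 * p1) if np.isfinite(lp1) else -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(40):
        eps *= 2.0 ** direction
        _, p1, lp1, _ = _leapfrog(logp_and_grad, theta, p, eps, 1, inv_mass, grad0)
        h1 = lp1 - 0.5 * np.sum(inv_mass * p1 * p1) if np.isfinite(lp1) else -np.inf
        if direction * (h1 - h0) < direction * np.log(0.5):
            break
    return eps


def _run_chain(logp_and_grad, theta0, n_warmup, n_samples, rng,
               max_leapfrog, target_accept):
    dim = theta0.size
    theta = theta0.copy()
    lp, grad = logp_and_grad(theta)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log-posterior")
    inv_mass = np.ones(dim)

    eps = _find_initial_step(logp_and_grad, theta, inv_mass, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # mass-adaptation windows within warmup
    w1, w2 = int(0.4 * n_warmup), int(0.8 * n_warmup)
    buffer = []

    draws = np.empty((n_samples, dim))
    n_acc = 0
    n_div = 0
    n_total = n_warmup + n_samples
    da_iter = 0
    for it in range(n_total):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        n_steps = int(rng.integers(1, max_leapfrog + 1))
        h0 = lp - 0.5 * np.sum(inv_mass * p0 * p0)
        theta_new, p_new, lp_new, grad_new = _leapfrog(
            logp_and_grad, theta, p0, eps, n_steps, inv_mass, grad
        )
        if np.isfinite(lp_new):
            h1 = lp_new - 0.5 * np.sum(inv_mass * p_new * p_new)
            log_alpha = min(0.0, h1 - h0)
            if (h0 - h1) > 1000.0:
                n_div += 1
        else:
            log_alpha = -np.inf
            n_div += 1
        accept_prob = np.exp(log_alpha)
        if rng.random() < accept_prob:
            theta, lp, grad = theta_new, lp_new, grad_new
            if it >= n_warmup:
                n_acc += 1

        if it < n_warmup:
            da_iter += 1
            h_bar = (1 - 1 / (da_iter + t0)) * h_bar + (
                target_accept - accept_prob
            ) / (da_iter + t0)
            log_eps = mu - np.sqrt(da_iter) / gamma * h_bar
            w = da_iter ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = np.exp(log_eps)
            if w1 <= it < w2:
                buffer.append(theta.copy())
            if it == w2 and len(buffer) > 10:
                var = np.var(np.asarray(buffer), axis=0)
                inv_mass = np.where(var > 1e-12, var, 1e-12)
                # restart step-size adaptation under the new metric
                eps = _find_initial_step(logp_and_grad, theta, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_iter = np.log(eps), 0.0, 0
            if it == n_warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            draws[it - n_warmup] = theta

    return draws, n_acc / max(n_samples, 1), eps, n_div


def run_hmc(logp_and_grad, theta0, n_warmup=500, n_samples=500, n_chains=2,
            seed=0, max_leapfrog=24, target_accept=0.8, init_jitter=0.05):
    """Run ``n_chains`` HMC chains from jittered starts; deterministic in seed."""
    theta0 = np.asarray(theta0, dtype=float)
    streams = np.random.SeedSequence(seed).spawn(n_chains)
    all_draws = np.empty((n_chains, n_samples, theta0.size))
    acc, div = [], 0
    eps_final = np.nan
    for c, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        start = theta0 + init_jitter * rng.standard_normal(theta0.size)
        draws, a, eps_final, nd = _run_chain(
            logp_and_grad, start, n_warmup, n_samples, rng,
            max_leapfrog, target_accept,
        )
        all_draws[c] = draws
        acc.append(a)
        div += nd
    if div > 0.01 * n_chains * (n_warmup + n_samples):
        warnings.warn(f"{div} divergent transitions during sampling", stacklevel=2)
    return HMCDraws(all_draws, float(np.mean(acc)), float(eps_final), div)


def convergence_table(draws_by_name: dict) -> "pd.DataFrame":
    """Split-R-hat / ESS / quantile summary per named parameter.

    ``draws_by_name`` maps parameter name -> array of shape (chain, draw).
    """
    import pandas as pd

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        rows = []
        for name, arr in draws_by_name.items():
            flat = arr.reshape(-1)
            rows.append({
                "parameter": name,
                "mean": flat.mean(),
                "sd": flat.std(ddof=1),
                "q2.5": np.quantile(flat, 0.025),
                "median": np.quantile(flat, 0.5),
                "q97.5": np.quantile(flat, 0.975),
                "rhat": float(az.rhat(arr[None] if arr.ndim == 1 else arr)
                              if arr.ndim > 1 else np.nan),
                "ess": float(az.ess(arr[None] if arr.ndim == 1 else arr)
                             if arr.ndim > 1 else np.nan),
            })
    return pd.DataFrame(rows)
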