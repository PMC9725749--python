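"""Unconstrained reparameterizations for HMC.

Simplex parameters (M-spline weights with Dirichlet priors) use the
stick-breaking transform with analytic log-Jacobian and vector-Jacobian
product; correlation matrices (LKJ priors) use the tanh
canonical-partial-correlation Cholesky construction, with the (tiny, data
independent) transform Jacobian obtained by central finite differences.
Positive scales are sampled on the log scale with the prior density
including the Jacobian ``+ log(scale)``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "stick_breaking",
    "stick_breaking_vjp",
    "corr_cholesky",
    "corr_logprior_and_grad",
    "corr_chol_grad_y",
    "log_halfcauchy",
    "log_halfnormal",
]


# ------------------------------------------------------------------ simplex

def stick_breaking(y):
    """Map R^m -> interior of the m-simplex (m+1 weights), with log-Jacobian.

    Returns ``(a, logJ)``; with a flat Dirichlet(1) prior the target density
    in y is simply ``exp(logJ)``.
    """
    y = np.asarray(y, dtype=float)
    m = y.size
    z = expit(y - np.log(m - np.arange(m)))
    one_minus = 1.0 - z
    r = np.concatenate(([1.0], np.cumprod(one_minus)))  # r_k, k=0..m
    a = np.empty(m + 1)
    a[:m] = z * r[:m]
    a[m] = r[m]
    logJ = float(np.sum(np.log(z) + np.log(one_minus) + np.log(r[:m])))
    return a, logJ


def stick_breaking_vjp(y, g_a):
    """Gradient in y of ``f(a(y)) + logJ(y)`` given ``g_a = df/da``.

    Returns ``(a, logJ, g_y)``.
    """
    y = np.asarray(y, dtype=float)
    g_a = np.asarray(g_a, dtype=float)
    m = y.size
    z = expit(y - np.log(m - np.arange(m)))
    one_minus = 1.0 - z
    r = np.concatenate(([1.0], np.cumprod(one_minus)))
    a = np.empty(m + 1)
    a[:m] = z * r[:m]
    a[m] = r[m]
    logJ = float(np.sum(np.log(z) + np.log(one_minus) + np.log(r[:m])))
    ga_a = g_a * a
    # S_j = sum_{k > j} g_k a_k  (k up to m)
    S = np.cumsum(ga_a[::-1])[::-1][1:]  # S_j, j = 0..m-1
    g_z = g_a[:m] * r[:m] - S / one_minus
    g_z += 1.0 / z - 1.0 / one_minus - (m - 1 - np.arange(m)) / one_minus
    g_y = g_z * z * one_minus
    return a, logJ, g_y


# -------------------------------------------------------------- correlations

def _corr_cholesky_batch(Y, d):
    """Batched CPC -> Cholesky transform: Y (B, m) -> L (B, d, d)."""
    Z = np.tanh(Y)
    B = Z.shape[0]
    L = np.zeros((B, d, d))
    L[:, 0, 0] = 1.0
    idx = 0
    for i in range(1, d):
        acc = np.ones(B)
        for j in range(i):
            L[:, i, j] = Z[:, idx] * np.sqrt(acc)
            acc = acc - L[:, i, j] ** 2
            idx += 1
        L[:, i, i] = np.sqrt(np.maximum(acc, 1e-300))
    return L


def corr_cholesky(y, d):
    """Cholesky factor of a correlation matrix from d(d-1)/2 unconstrained values."""
    y = np.asarray(y, dtype=float)
    return _corr_cholesky_batch(y[None, :], d)[0]


def _offdiag(L, d):
    return np.array([L[i, j] for i in range(1, d) for j in range(i)])


def _corr_log_target_batch(Y, d, eta):
    """LKJ(eta) log-density of Omega(y) plus log |d offdiag(Omega)/dy|.

    The y -> offdiag(Omega) Jacobian is triangular in the row-major CPC
    ordering, so its log-determinant is a sum of the diagonal terms
    ``log L_jj + 0.5 log acc_ij`` plus the tanh Jacobian. Batched over
    rows of ``Y``.
    """
    Z = np.tanh(Y)
    B = Z.shape[0]
    L = _corr_cholesky_batch(Y, d)
    diag = L[:, np.arange(d), np.arange(d)]
    t = (eta - 1.0) * 2.0 * np.sum(np.log(diag), axis=1)
    idx = 0
    for i in range(1, d):
        acc = np.ones(B)
        for j in range(i):
            t += np.log(L[:, j, j]) + 0.5 * np.log(acc) + np.log1p(-Z[:, idx] ** 2)
            acc = acc - L[:, i, j] ** 2
            idx += 1
    return t


def _corr_log_target(y, d, eta):
    return float(_corr_log_target_batch(np.asarray(y, float)[None, :], d, eta)[0])


def _fd_batch(y, h):
    """Stack of y +/- h e_q perturbations: (2m, m); plus-first ordering."""
    m = y.size
    E = h * np.eye(m)
    return np.concatenate([y[None, :] + E, y[None, :] - E], axis=0)


def corr_logprior_and_grad(y, d, eta=2.0):
    """LKJ(eta) log-prior in the unconstrained space, with FD gradient."""
    y = np.asarray(y, dtype=float)
    m = y.size
    h = 1e-5
    Y = np.concatenate([y[None, :], _fd_batch(y, h)], axis=0)
    vals = _corr_log_target_batch(Y, d, eta)
    g = (vals[1:1 + m] - vals[1 + m:]) / (2 * h)
    return float(vals[0]), g


def corr_chol_grad_y(y, d, G_L):
    """Chain ``dL/dy`` (FD) against an analytic data gradient ``G_L``."""
    y = np.asarray(y, dtype=float)
    m = y.size
    h = 1e-6
    Ls = _corr_cholesky_batch(_fd_batch(y, h), d)
    dL = (Ls[:m] - Ls[m:]) / (2 * h)
    return np.einsum("qij,ij->q", dL, G_L)


# -------------------------------------------------------------------- scales

def log_halfcauchy(log_s, scale=1.0):
    """log-density of HalfCauchy(0, scale) for s = exp(log_s), incl. Jacobian.

    Returns ``(logp, dlogp/dlog_s)`` elementwise.
    """
    s = np.exp(np.asarray(log_s, dtype=float))
    u = (s / scale) ** 2
    logp = np.log(2.0 / (np.pi * scale)) - np.log1p(u) + np.log(s)
    grad = 1.0 - 2.0 * u / (1.0 + u)
    return logp, grad


def log_halfnormal(log_s, scale=1.0):
    """log-density of HalfNormal(0, scale) for s = exp(log_s), incl. Jacobian."""
    s = np.exp(np.asarray(log_s, dtype=float))
    logp = 0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (s / scale) ** 2 + np.log(s)
    grad = 1.0 - (s / scale) ** 2
    return logp, grad
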