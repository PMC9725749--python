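"""Softplus link and its inverse/derivative.

The damage/repair rate models use a Softplus link, ``softplus(x) = log(1 + e^x)``,
to enforce positive rates while staying asymptotically linear for large
linear predictors (an exponential link over-amplifies covariate effects in
these count models).
"""

from __future__ import annotations

import numpy as np

__all__ = ["softplus", "softplus_inverse", "softplus_derivative"]


def softplus(x):
    """Overflow-safe ``log(1 + exp(x))``, elementwise."""
    x = np.asarray(x, dtype=float)
    # log1p(exp(-|x|)) + max(x, 0) is stable at both tails
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def softplus_inverse(y):
    """Inverse of :func:`softplus`: ``log(exp(y) - 1)`` for y > 0.

    Raises
    ------
    ValueError
        If any element of ``y`` is not strictly positive.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("softplus_inverse requires strictly positive input")
    # log(e^y - 1) = y + log(1 - e^-y); stable for large y, accurate for small
    with np.errstate(divide="ignore"):
        out = y + np.log(-np.expm1(-y))
    return out


def softplus_derivative(x):
    """d/dx softplus(x) = logistic sigmoid, elementwise."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
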