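"""M-spline / I-spline bases for baseline hazards and tensor B-spline surfaces.

M-splines are non-negative spline basis functions that each integrate to one
over the knot span; a simplex-weighted combination of them is therefore a
probability-density-shaped baseline hazard. Their running integrals
(I-splines) are monotone from 0 to 1 and give closed-form cumulative hazards.

All bases here are order 3 (quadratic pieces), clamped at the boundary
knots. A knot vector with ``K`` distinct values carries ``K + 1`` basis
functions under this construction.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "MSplineBasis",
    "bspline_basis_1d",
    "make_knots_mouse",
    "make_knots_state",
    "make_knots_surface",
    "tensor_surface_design",
]

ORDER = 3  # spline order (degree 2)


class KnotError(ValueError):
    """Raised when input times cannot support the requested knot rule."""


def _check_distinct(times, needed: int, what: str) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    distinct = np.unique(times)
    if distinct.size < needed:
        raise KnotError(
            f"{what} requires at least {needed} distinct times, got {distinct.size}"
        )
    return times


def make_knots_mouse(last_followup_times) -> np.ndarray:
    """Knot vector for the mouse baseline hazard: 17 knots.

    Knots sit at the minimum and maximum last-follow-up time plus 15
    uniformly spaced quantiles from 0.05 to 0.95.
    """
    times = _check_distinct(last_followup_times, 17, "mouse baseline knot rule")
    qs = np.linspace(0.05, 0.95, 15)
    knots = np.concatenate(
        ([times.min()], np.quantile(times, qs), [times.max()])
    )
    return _dedupe_knots(knots)


def make_knots_state(event_times) -> np.ndarray:
    """Knot vector for deficit-state survival: 32 knots.

    30 evenly spaced quantiles of representative event times from 0.1 to
    0.9, plus the minimum and maximum.
    """
    times = _check_distinct(event_times, 32, "state-survival knot rule")
    qs = np.linspace(0.1, 0.9, 30)
    knots = np.concatenate(
        ([times.min()], np.quantile(times, qs), [times.max()])
    )
    return _dedupe_knots(knots)


def make_knots_surface(values) -> np.ndarray:
    """Knots for one axis of a varying-coefficient surface.

    Minimum, terciles and maximum of the observed variable: 4 distinct knot
    values, carrying exactly 5 clamped order-3 B-spline basis functions.
    """
    values = np.asarray(values, dtype=float)
    knots = np.quantile(values, [0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0])
    return _dedupe_knots(knots)


def _dedupe_knots(knots: np.ndarray) -> np.ndarray:
    """Strictly increasing knot vector; ties broken by a tiny jitter."""
    knots = np.sort(np.asarray(knots, dtype=float))
    if np.unique(knots).size != knots.size:
        raise KnotError("degenerate knot vector: duplicate knot values")
    return knots


def _full_knot_sequence(knots: np.ndarray, order: int = ORDER) -> np.ndarray:
    return np.concatenate(
        (np.repeat(knots[0], order - 1), knots, np.repeat(knots[-1], order - 1))
    )


def _bspline_design(x, knots: np.ndarray, order: int = ORDER) -> np.ndarray:
    """Dense design matrix of clamped B-spline basis values at ``x``."""
    t = _full_knot_sequence(knots, order)
    x = np.clip(np.asarray(x, dtype=float), knots[0], knots[-1])
    dm = BSpline.design_matrix(x, t, order - 1, extrapolate=False)
    return np.asarray(dm.todense())


def bspline_basis_1d(x, knots) -> np.ndarray:
    """Clamped order-3 B-spline basis values (partition of unity).

    Out-of-span queries are clamped to the boundary with a warning.
    """
    knots = np.asarray(knots, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(x < knots[0]) or np.any(x > knots[-1]):
        warnings.warn("query outside knot span; clamping to boundary", stacklevel=2)
    return _bspline_design(x, knots)


def tensor_surface_design(w, a0, knots_w, knots_a0) -> np.ndarray:
    """Row-wise tensor product basis for a 2D varying-coefficient surface.

    Returns an array of shape ``(len(w), nb_w * nb_a0)`` whose dot product
    with a flattened coefficient grid ``s_ij`` evaluates the surface
    ``sum_ij s_ij B_i(w) B_j(a0)`` at each point.
    """
    Bw = bspline_basis_1d(w, knots_w)
    Ba = bspline_basis_1d(a0, knots_a0)
    return np.einsum("ni,nj->nij", Bw, Ba).reshape(len(Bw), -1)


class MSplineBasis:
    """Order-3 M-spline family on a distinct knot vector.

    Each basis function is non-negative and integrates to 1 over the knot
    span, so simplex-weighted combinations are hazard shapes. Evaluation
    outside the span clamps to the boundary value (constant extrapolation);
    the running integral accounts for that flat extension, taking time 0 as
    the origin when integrating below the span.
    """

    def __init__(self, knots):
        self.knots = np.asarray(knots, dtype=float)
        if self.knots.ndim != 1 or self.knots.size < 2:
            raise KnotError("need at least two knots")
        if np.any(np.diff(self.knots) <= 0):
            raise KnotError("knots must be strictly increasing")
        self._t = _full_knot_sequence(self.knots)
        deg = ORDER - 1
        n_basis = len(self._t) - ORDER
        self.n_basis = n_basis
        # M-spline scale: order / (t[i+order] - t[i]); each then integrates to 1
        denom = self._t[ORDER:] - self._t[:n_basis]
        self._scale = ORDER / denom
        # antiderivative spline per basis element for I-splines
        self._antider = []
        for l in range(n_basis):
            c = np.zeros(n_basis)
            c[l] = 1.0
            self._antider.append(BSpline(self._t, c, deg).antiderivative())
        self._boundary_lo = self._eval_in_span(np.array([self.knots[0]]))[0]
        self._boundary_hi = self._eval_in_span(np.array([self.knots[-1]]))[0]

    def _eval_in_span(self, x: np.ndarray) -> np.ndarray:
        return _bspline_design(x, self.knots) * self._scale

    def evaluate(self, x) -> np.ndarray:
        """M-spline basis values, shape (len(x), n_basis); clamped outside span."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return self._eval_in_span(np.clip(x, self.knots[0], self.knots[-1]))

    def integral(self, x) -> np.ndarray:
        """``int_0^x`` of each (clamped) basis function, shape (len(x), n_basis).

        Inside the span this is the I-spline; the clamped flat extensions
        below/above the span contribute linear terms. Assumes the knot span
        lies at non-negative times (state-entry clocks start at zero).
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.knots[0], self.knots[-1]
        xc = np.clip(x, lo, hi)
        ispl = np.column_stack(
            [f(xc) - f(lo) for f in self._antider]
        ) * self._scale
        below = np.clip(np.minimum(x, lo), 0.0, lo if lo > 0 else 0.0)
        over = np.clip(x - hi, 0.0, None)
        return ispl + below[:, None] * self._boundary_lo + over[:, None] * self._boundary_hi
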