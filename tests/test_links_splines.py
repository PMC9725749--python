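"""Softplus link and spline bases."""

import numpy as np
import pytest

from frailtydynamics.links import softplus, softplus_derivative, softplus_inverse
from frailtydynamics.splines import (
    KnotError,
    MSplineBasis,
    bspline_basis_1d,
    make_knots_mouse,
    make_knots_state,
    make_knots_surface,
    tensor_surface_design,
)


class TestSoftplus:
    def test_closed_form_values(self):
        assert softplus(0.0) == pytest.approx(np.log(2), abs=1e-12)
        assert softplus(40.0) - 40.0 < 1e-15  # asymptotically linear

    def test_round_trip(self):
        x = np.linspace(-18, 50, 200)  # y in ~[1e-8, 50]
        assert np.abs(softplus_inverse(softplus(x)) - x).max() < 1e-10

    def test_inverse_domain_error(self):
        with pytest.raises(ValueError):
            softplus_inverse(np.array([0.5, -0.1]))

    def test_derivative_is_sigmoid(self):
        x = np.linspace(-30, 30, 101)
        fd = (softplus(x + 1e-6) - softplus(x - 1e-6)) / 2e-6
        assert np.abs(softplus_derivative(x) - fd).max() < 1e-6


class TestKnotRules:
    def test_mouse_rule_17_knots(self):
        t = np.linspace(0, 1, 100)
        k = make_knots_mouse(t)
        assert len(k) == 17
        assert k[0] == 0.0 and k[-1] == 1.0
        # uniform input: interior quantiles land on the quantile levels
        assert np.allclose(k[1:-1], np.linspace(0.05, 0.95, 15), atol=1e-9)

    def test_state_rule_32_knots(self):
        k = make_knots_state(np.linspace(0.5, 9.5, 1000))
        assert len(k) == 32

    @pytest.mark.parametrize("rule,n_needed", [(make_knots_mouse, 17), (make_knots_state, 32)])
    def test_too_few_distinct_times(self, rule, n_needed):
        with pytest.raises(KnotError):
            rule(np.repeat(np.arange(n_needed - 1), 5))

    def test_surface_rule_terciles(self):
        v = np.linspace(2, 8, 300)
        k = make_knots_surface(v)
        assert len(k) == 4
        assert np.allclose(k, [2, 4, 6, 8], atol=0.05)


@pytest.fixture(scope="module")
def basis():
    return MSplineBasis(make_knots_mouse(np.linspace(0, 10, 60)))


class TestMSplines:

    def test_non_negative_and_unit_integral(self, basis):
        x = np.linspace(0, 10, 4001)
        vals = basis.evaluate(x)
        assert vals.min() >= 0
        assert np.abs(np.trapezoid(vals, x, axis=0) - 1).max() < 1e-3

    def test_isplines_monotone_zero_to_one(self, basis):
        x = np.linspace(0, 10, 400)
        I = basis.integral(x)
        assert np.all(np.diff(I, axis=0) >= -1e-12)
        assert np.abs(I[-1] - 1).max() < 1e-9
        assert np.abs(I[0]).max() < 1e-12

    def test_clamped_extrapolation_integral(self, basis):
        # beyond the span the hazard is held at its boundary value
        I = basis.integral(np.array([10.0, 12.0]))
        boundary = basis.evaluate(np.array([10.0]))[0]
        assert np.allclose(I[1] - I[0], 2.0 * boundary, atol=1e-10)


def _cox_de_boor(x, t, i, k):
    """Brute-force B-spline recursion oracle (order k = degree + 1)."""
    if k == 1:
        # right-closed at the final knot so the clamped end evaluates to 1
        if t[i] <= x < t[i + 1] or (x == t[-1] and t[i + 1] == t[-1] and t[i] < t[i + 1]):
            return 1.0
        return 0.0
    out = 0.0
    if t[i + k - 1] > t[i]:
        out += (x - t[i]) / (t[i + k - 1] - t[i]) * _cox_de_boor(x, t, i, k - 1)
    if t[i + k] > t[i + 1]:
        out += (t[i + k] - x) / (t[i + k] - t[i + 1]) * _cox_de_boor(x, t, i + 1, k - 1)
    return out


class TestSurfaceBasis:
    def test_five_basis_functions_per_axis(self):
        knots = np.array([0.0, 1.0, 2.0, 3.0])
        B = bspline_basis_1d(np.linspace(0, 3, 7), knots)
        assert B.shape[1] == 5

    def test_partition_of_unity_and_constant_surface(self):
        kw = np.array([0.0, 1.0, 2.0, 3.0])
        ka = np.array([50.0, 60.0, 70.0, 90.0])
        w = np.linspace(0, 3, 11)
        a = np.linspace(50, 90, 11)
        T = tensor_surface_design(w, a, kw, ka)
        c = 2.7
        assert np.allclose(T @ np.full(25, c), c, atol=1e-12)

    def test_single_cell_nonneg_compact_support(self):
        kw = np.array([0.0, 1.0, 2.0, 3.0])
        s = np.zeros(25)
        s[12] = 1.0
        w = np.linspace(0, 3, 41)
        T = tensor_surface_design(w, w * 10 + 50,
                                  kw, kw * 10 + 50)
        vals = T @ s
        assert vals.min() >= 0
        assert (vals == 0).any() and vals.max() > 0

    def test_matches_cox_de_boor_oracle(self):
        knots = np.array([0.0, 0.7, 1.9, 3.0])
        full = np.concatenate(([0.0, 0.0], knots, [3.0, 3.0]))
        xs = np.linspace(0, 3, 53)
        B = bspline_basis_1d(xs, knots)
        oracle = np.array([[_cox_de_boor(x, full, i, 3) for i in range(5)] for x in xs])
        assert np.abs(B - oracle).max() < 1e-10

    def test_smoothness_by_finite_differences(self):
        # order-3 (quadratic) surfaces are C1: first differences converge
        knots = np.array([0.0, 1.0, 2.0, 3.0])
        s = np.sin(np.arange(25))
        x = np.linspace(0.1, 2.9, 301)
        vals = tensor_surface_design(x, np.full_like(x, 1.5),
                                     knots, knots) @ s
        d1 = np.diff(vals)
        assert np.abs(np.diff(d1)).max() < 5e-3  # no jumps in value or slope
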