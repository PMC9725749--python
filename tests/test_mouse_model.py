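"""Joint longitudinal-survival model for mice."""

import numpy as np
import pandas as pd
import pytest

from frailtydynamics import GroundTruth, MouseJointModel, count_transitions, simulate_cohort
from frailtydynamics.mcmc import ConvergenceError
from frailtydynamics.mouse import (
    expected_fixed_effects,
    gauss_legendre_cumhaz,
    longitudinal_loglik,
)
from frailtydynamics.simulate import simulate_poisson_counts


class TestLongitudinalLoglik:
    def test_zero_items_zero_count_contributes_nothing(self, mouse_counts):
        d = mouse_counts.data.iloc[:1].copy()
        d.loc[:, ["n", "n_repair"]] = 0
        d.loc[:, "n_damage"] = 0
        d.loc[:, "n_next"] = 0
        c = mouse_counts.__class__(d, n_items=mouse_counts.n_items)
        ll_all = longitudinal_loglik(c, np.array([0.5]), np.array([1e-300]))
        # repair term is exactly 0 (Poisson(0) at 0); damage term ~ -mu ~ 0
        assert ll_all == pytest.approx(0.0, abs=1e-6)

    def test_poisson_closed_form(self):
        # one interval: n lambda_r dt = 2 with n_r = 2
        d = pd.DataFrame([{
            "subject_id": "s", "time": 0.0, "dt": 1.0, "n": 4,
            "n_repair": 2, "n_damage": 0, "n_next": 2,
        }])
        from frailtydynamics.transitions import TransitionCounts

        c = TransitionCounts(d, n_items=10)
        ll = longitudinal_loglik(c, np.array([0.5]), np.array([1e-300]))
        expected = np.log(2.0 ** 2 * np.exp(-2.0) / 2.0)
        assert ll == pytest.approx(expected, abs=1e-6)

    def test_mle_consistency_on_simulation(self):
        counts, _ = simulate_poisson_counts(
            GroundTruth(re_sd=np.zeros(4)), 400, seed=21
        )
        d = counts.data
        # crude pooled MLE of the repair rate vs the population mean rate
        lam_hat = d["n_repair"].sum() / (d["n"] * d["dt"]).sum()
        from frailtydynamics.design import mouse_raw_design
        from frailtydynamics.links import softplus

        fi = d["n"].to_numpy(float) / counts.n_items
        X = mouse_raw_design(d["time"], d["sex"], d["treatment"], fi, d["baseline_age"])
        lam_true = softplus(X @ GroundTruth().beta_r)
        w = (d["n"] * d["dt"]).to_numpy(float)
        lam_bar = np.average(lam_true, weights=w)
        se = np.sqrt(d["n_repair"].sum()) / (d["n"] * d["dt"]).sum()
        assert abs(lam_hat - lam_bar) < 4 * se


class TestQuadrature:
    def test_constant_hazard_exact(self):
        assert gauss_legendre_cumhaz(lambda t: np.full_like(t, 3.0), [0, 1, 2, 5]) \
            == pytest.approx(15.0, abs=1e-12)

    def test_cubic_exact_to_machine_precision(self):
        poly = lambda t: 2 + t + 0.5 * t ** 2 + 0.1 * t ** 3
        exact = lambda t: 2 * t + t ** 2 / 2 + 0.5 * t ** 3 / 3 + 0.1 * t ** 4 / 4
        val = gauss_legendre_cumhaz(poly, [0.0, 1.3, 4.0])
        assert val == pytest.approx(exact(4.0), abs=1e-12)


class TestFitContract:
    def test_same_seed_identical_draws(self, mouse_counts, mouse_cohort):
        m = MouseJointModel(mouse_counts, mouse_cohort.panel.survival)
        a = m.fit(n_warmup=30, n_samples=30, seed=3, on_bad_convergence="warn")
        b = m.fit(n_warmup=30, n_samples=30, seed=3, on_bad_convergence="warn")
        for k in a.posterior.draws:
            assert np.array_equal(a.posterior.draws[k], b.posterior.draws[k])

    def test_nonconvergence_raises(self, mouse_counts, mouse_cohort):
        m = MouseJointModel(mouse_counts, mouse_cohort.panel.survival)
        from frailtydynamics.mcmc import run_hmc
        with pytest.raises(ConvergenceError):
            # starved warmup from dispersed starts cannot pass the R-hat gate
            res = run_hmc(m._logp_and_grad, m._initial_point(),
                          n_warmup=5, n_samples=40, n_chains=2, seed=0,
                          init_jitter=2.0)
            post = m._to_posterior(res.draws)
            from frailtydynamics.mouse import MouseJointResults
            r = MouseJointResults(m, post, res)
            bad = r.check_convergence(1.05)
            if bad:
                raise ConvergenceError(str(bad))

    def test_dimension_mismatch_errors(self, mouse_counts):
        surv = pd.DataFrame({
            "subject_id": ["nobody"], "death_time": [1.0], "censored": [0],
        }).set_index("subject_id")
        with pytest.raises(ValueError, match="survival records missing"):
            MouseJointModel(mouse_counts, surv)


class TestPosteriorStructure:
    def test_simplex_and_correlation_draws_valid(self, mouse_fit):
        post = mouse_fit.posterior
        for name in ("a_male", "a_female"):
            a = post.flat(name)
            assert a.min() >= 0
            assert np.allclose(a.sum(axis=1), 1.0, atol=1e-10)
        Om = post.flat("Omega")
        assert np.allclose(Om[:, np.arange(4), np.arange(4)], 1.0, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(Om).min(axis=1) > -1e-12)

    def test_survival_draws_monotone_from_one(self, mouse_fit, mouse_cohort):
        sid = mouse_fit.model.design.subject_ids[0]
        times = np.sort(
            mouse_cohort.panel.observations.query("subject_id == @sid")["time"].unique()
        )
        S = mouse_fit.survival_draws(sid, times)
        assert np.allclose(S[:, 0], 1.0, atol=1e-12)  # S(t0) = 1
        assert np.all(np.diff(S, axis=1) <= 1e-12)


class TestRecoveryOracle:
    def test_effective_rate_projection_reduces_to_identity_at_small_rates(self):
        # when lambda * dt << 1 the discretized estimand equals the raw one
        truth = GroundTruth(
            beta_r=np.concatenate(([-6.0], np.zeros(9))),
            beta_d=np.concatenate(([-6.5], np.zeros(9))),
            re_sd=np.zeros(4),
        )
        cohort = simulate_cohort(truth, 30, seed=14)
        counts = count_transitions(cohort.panel)
        m = MouseJointModel(counts, cohort.panel.survival)
        exp = expected_fixed_effects(truth, m)
        from frailtydynamics.design import map_coefficients, mouse_raw_design

        d = counts.data
        fi = d["n"].to_numpy(float) / m.N
        X_raw = mouse_raw_design(d["time"], d["sex"], d["treatment"], fi, d["baseline_age"])
        raw_map = map_coefficients(truth.beta_r, X_raw, m.X)
        # first-order discretization term is lambda*dt/2 ~ 2e-3 on the link
        # scale at these rates; the projection must agree to that order
        assert np.abs(exp["beta_r"] - raw_map).max() < 5e-3


def test_poisson_only_variant_matches_joint_when_no_deaths():
    """With everyone censored and gamma loadings near prior, removing the
    survival component leaves the longitudinal posterior unchanged within
    Monte Carlo error (modularity)."""
    counts, surv = simulate_poisson_counts(GroundTruth(), 50, seed=31)
    joint = MouseJointModel(counts, surv, include_survival=True)
    plain = MouseJointModel(counts, surv, include_survival=False)
    rj = joint.fit(n_warmup=250, n_samples=250, seed=5, on_bad_convergence="warn")
    rp = plain.fit(n_warmup=250, n_samples=250, seed=6, on_bad_convergence="warn")
    for name in ("beta_r", "beta_d"):
        mj = rj.posterior.flat(name).mean(axis=0)
        mp = rp.posterior.flat(name).mean(axis=0)
        sd = rj.posterior.flat(name).std(axis=0)
        assert np.all(np.abs(mj - mp) < 4 * sd / np.sqrt(10) + 0.05)
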