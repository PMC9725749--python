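"""Deficit-state lifetimes: extraction, likelihood, fits, log-rank test."""

import numpy as np
import pandas as pd
import pytest

from frailtydynamics.statesurv import (
    GroupingError,
    StateSurvivalModel,
    extract_state_intervals,
    generalized_logrank,
    interval_censored_loglik,
    turnbull_npmle,
)
from tests.test_preprocess import make_panel


def sim_records(n, h, seed, visit_gap=1.0, horizon=12.0, label=None):
    """Exponential lifetimes observed on a visit grid -> interval/right censored."""
    rng = np.random.default_rng(seed)
    grid = np.arange(0.0, horizon + 1e-9, visit_gap)
    rows = []
    for _ in range(n):
        T = rng.exponential(1.0 / h)
        if T > horizon:
            rows.append({"censored": 1, "t_censor": horizon,
                         "t_lower": np.nan, "t_upper": np.nan})
        else:
            j = int(np.searchsorted(grid, T))
            rows.append({"censored": 0, "t_lower": grid[j - 1],
                         "t_upper": grid[j], "t_censor": np.nan})
    df = pd.DataFrame(rows)
    if label is not None:
        df["group"] = label
    return df


class TestExtraction:
    def test_interval_exit_bounds(self):
        p = make_panel({"d0": [0, 1, 1, 0]})
        rec = extract_state_intervals(p)
        damaged = rec[rec["state"] == "damaged"].iloc[0]
        assert damaged["entry_time"] == 1.0
        assert (damaged["t_lower"], damaged["t_upper"]) == (1.0, 2.0)
        assert damaged["censored"] == 0

    def test_right_censoring_at_last_visit(self):
        p = make_panel({"d0": [0, 1, 1]})
        rec = extract_state_intervals(p)
        damaged = rec[rec["state"] == "damaged"].iloc[0]
        assert damaged["censored"] == 1
        assert damaged["t_censor"] == 1.0  # last visit 2 minus entry 1

    def test_initial_state_excluded(self):
        rec = extract_state_intervals(make_panel({"d0": [1, 1, 1]}))
        assert len(rec) == 0

    def test_midpoint_entry_option(self):
        p = make_panel({"d0": [0, 1, 1, 0]})
        rec = extract_state_intervals(p, entry_convention="midpoint")
        damaged = rec[rec["state"] == "damaged"].iloc[0]
        assert damaged["entry_time"] == 0.5

    def test_undamaged_spell_after_repair(self):
        p = make_panel({"d0": [1, 0, 0, 1]})
        rec = extract_state_intervals(p)
        und = rec[rec["state"] == "undamaged"].iloc[0]
        assert und["entry_time"] == 1.0
        assert (und["t_lower"], und["t_upper"]) == (1.0, 2.0)


class TestLoglik:
    def test_total_mass_is_zero_loglik(self):
        rec = pd.DataFrame([{"censored": 0, "t_lower": 0.0, "t_upper": 1e9,
                             "t_censor": np.nan}])
        ll = interval_censored_loglik(rec, lambda t: np.exp(-np.asarray(t)))
        assert ll == pytest.approx(0.0, abs=1e-6)

    def test_censored_exponential(self):
        rec = pd.DataFrame([{"censored": 1, "t_censor": 2.0,
                             "t_lower": np.nan, "t_upper": np.nan}])
        ll = interval_censored_loglik(rec, lambda t: np.exp(-np.asarray(t)))
        assert ll == pytest.approx(-2.0, abs=1e-12)

    def test_bad_interval_rejected(self):
        rec = pd.DataFrame([{"censored": 0, "t_lower": 2.0, "t_upper": 1.0,
                             "t_censor": np.nan}])
        with pytest.raises(ValueError):
            interval_censored_loglik(rec, lambda t: np.exp(-np.asarray(t)))


class TestBayesianFit:
    def test_requires_an_event(self):
        rec = sim_records(20, 0.001, 0, horizon=1.0)
        if (rec["censored"] == 0).any():
            rec = rec[rec["censored"] == 1]
        with pytest.raises(ValueError, match="uncensored"):
            StateSurvivalModel(rec)

    def test_constant_hazard_truth_within_band(self):
        h = 0.3
        rec = sim_records(400, h, seed=2)
        res = StateSurvivalModel(rec).fit(
            n_warmup=300, n_samples=300, seed=3, on_bad_convergence="warn"
        )
        tg = np.linspace(0.5, 10.0, 20)
        band = res.survival_band(tg)
        truth = np.exp(-h * tg)
        assert ((band["lower"] <= truth) & (truth <= band["upper"])).mean() >= 0.9

    def test_survival_draws_monotone_from_one(self):
        rec = sim_records(150, 0.4, seed=5)
        res = StateSurvivalModel(rec).fit(
            n_warmup=200, n_samples=200, seed=1, on_bad_convergence="warn"
        )
        S = res.survival_draws(np.linspace(0.0, 8.0, 30))
        assert np.allclose(S[:, 0], 1.0, atol=1e-12)
        assert np.all(np.diff(S, axis=1) <= 1e-12)


class TestTurnbull:
    def test_probabilities_sum_to_one(self):
        tb = turnbull_npmle(sim_records(200, 0.25, seed=7))
        assert tb.prob.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(tb.weights.sum(axis=1), 1.0)

    def test_time_unit_equivariance(self):
        rec = sim_records(150, 0.3, seed=8)
        rec2 = rec.copy()
        for c in ("t_lower", "t_upper", "t_censor"):
            rec2[c] = rec2[c] * 2.0
        a = turnbull_npmle(rec)
        b = turnbull_npmle(rec2)
        assert np.allclose(b.intervals, 2.0 * a.intervals)
        assert np.allclose(b.prob, a.prob, atol=1e-8)

    def test_recovers_exponential_truth(self):
        # closed-form oracle: S at the lattice right edges is e^{-h k}
        h = 0.3
        rec = sim_records(600, h, seed=9)
        tb = turnbull_npmle(rec)
        ts = tb.intervals[:-1, 1]
        S_ours = 1.0 - np.cumsum(tb.prob)[:-1]
        S_true = np.exp(-h * ts)
        se = np.sqrt(S_true * (1 - S_true) / 600)
        assert np.all(np.abs(S_ours - S_true) < 4 * se + 0.01)


class TestLogrank:
    def test_identical_groups(self):
        rec = sim_records(80, 0.3, seed=10)
        dup = pd.concat([rec.assign(group="a"), rec.assign(group="b")],
                        ignore_index=True)
        stat, p = generalized_logrank(dup, "group", 199, seed=0)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == 1.0

    def test_single_group_rejected(self):
        rec = sim_records(50, 0.3, seed=11, label="only")
        with pytest.raises(GroupingError):
            generalized_logrank(rec, "group", 199, seed=0)

    def test_detects_doubled_hazard(self):
        both = pd.concat([
            sim_records(150, 0.3, seed=12, label="a"),
            sim_records(150, 0.6, seed=13, label="b"),
        ], ignore_index=True)
        _, p = generalized_logrank(both, "group", 499, seed=1)
        assert p < 0.05
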