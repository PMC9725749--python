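"""Synthetic-cohort generator: determinism, closed forms, survival draws."""

import numpy as np
import pandas as pd
import pytest

from frailtydynamics import (
    GroundTruth,
    count_transitions,
    simulate_cohort,
    simulate_human_cohort,
    HumanGroundTruth,
)
from frailtydynamics.simulate import (
    DefinitenessError,
    ScheduleError,
    SubjectState,
    simulate_survival,
)


def flat_truth(**over):
    """Truth with all dynamics switched off unless overridden."""
    base = dict(
        beta_r=np.concatenate(([-30.0], np.zeros(9))),
        beta_d=np.concatenate(([-30.0], np.zeros(9))),
        re_sd=np.zeros(4),
        gamma=np.zeros(6), gamma_r=0.0, gamma_d=0.0,
        base_hazard_male=np.zeros(3), base_hazard_female=np.zeros(3),
        initial_damage_prob=0.3,
        schedule=np.arange(0.0, 8.0, 1.0),
    )
    base.update(over)
    return GroundTruth(**base)


class TestValidation:
    def test_non_increasing_schedule(self):
        with pytest.raises(ScheduleError):
            GroundTruth(schedule=[0.0, 1.0, 1.0])

    def test_bad_correlation(self):
        C = np.full((4, 4), 0.99)
        np.fill_diagonal(C, 1.0)
        C[0, 1] = C[1, 0] = -0.99  # not PSD
        with pytest.raises(DefinitenessError):
            GroundTruth(re_corr=C)


class TestCohort:
    def test_zero_rates_freeze_fi(self):
        cohort = simulate_cohort(flat_truth(), 20, seed=5)
        c = count_transitions(cohort.panel)
        assert c.data[["n_damage", "n_repair"]].to_numpy().sum() == 0
        assert c.data["n"].nunique() <= 20  # constant within subject
        for _, g in c.data.groupby("subject_id"):
            assert g["n"].nunique() == 1

    def test_same_seed_identical(self):
        a = simulate_cohort(GroundTruth(), 15, seed=42)
        b = simulate_cohort(GroundTruth(), 15, seed=42)
        pd.testing.assert_frame_equal(a.panel.observations, b.panel.observations)
        pd.testing.assert_frame_equal(a.panel.survival, b.panel.survival)

    def test_counts_never_exceed_items(self, mouse_counts):
        d = mouse_counts.data
        assert (d["n_repair"] <= d["n"]).all()
        assert (d["n_damage"] <= mouse_counts.n_items - d["n"]).all()

    def test_death_after_last_observed_visit(self, mouse_cohort):
        surv = mouse_cohort.panel.survival
        last = mouse_cohort.panel.observations.groupby("subject_id")["time"].max()
        assert (surv["death_time"] + 1e-9 >= last.reindex(surv.index)).all()

    def test_equilibrium_occupancy(self):
        # constant equal rates -> per-item occupancy converges to 1/2
        lam = 0.3
        eta = np.log(np.exp(lam) - 1)
        truth = flat_truth(
            beta_r=np.concatenate(([eta], np.zeros(9))),
            beta_d=np.concatenate(([eta], np.zeros(9))),
            initial_damage_prob=0.05,
            n_items=40,
            schedule=np.arange(0.0, 61.0, 1.0),
        )
        cohort = simulate_cohort(truth, 300, seed=8)
        last = cohort.true_rates.groupby("subject_id")["fi"].last()
        m = last.mean()
        se = last.std(ddof=1) / np.sqrt(len(last))
        # binomial equilibrium lambda_d / (lambda_d + lambda_r) = 0.5
        assert abs(m - 0.5) < max(3 * se, 0.01)


def _const_state(times, sex=0.0):
    J = len(times)
    return SubjectState(
        times=times, fi=np.full(J, 0.2),
        eta_r=np.full(J, -2.0), eta_d=np.full(J, -4.0),
        eta_r_slope=np.zeros(J - 1), eta_d_slope=np.zeros(J - 1),
        sex=sex, treatment=0.0, baseline_age=16.0,
    )


class TestSurvival:
    def test_zero_hazard_censors_at_final_visit(self):
        truth = flat_truth()
        times = truth.schedule
        t, c = simulate_survival(truth, _const_state(times), seed=0)
        assert c == 1 and t == times[-1]

    def test_constant_hazard_matches_exponential(self):
        h = 0.15
        truth = flat_truth(
            base_hazard_male=np.full(3, h), base_hazard_female=np.full(3, h),
            schedule=np.arange(0.0, 30.0, 1.0),
        )
        times = truth.schedule
        draws = np.array([
            simulate_survival(truth, _const_state(times), seed=s)
            for s in range(1000)
        ])
        t_obs, cens = draws[:, 0], draws[:, 1]
        # empirical S(t) vs e^{-ht} within binomial CI at a few horizons
        for t0 in (2.0, 5.0, 10.0, 20.0):
            p_hat = np.mean(t_obs > t0 - 1e-9)
            p_true = np.exp(-h * t0)
            se = np.sqrt(p_true * (1 - p_true) / 1000)
            assert abs(p_hat - p_true) < 3.5 * se

    def test_lifelines_cross_check(self):
        # independent oracle: KM median of the simulated draws ~ log(2)/h
        from lifelines import KaplanMeierFitter

        h = 0.2
        truth = flat_truth(
            base_hazard_male=np.full(3, h), base_hazard_female=np.full(3, h),
            schedule=np.arange(0.0, 40.0, 1.0),
        )
        times = truth.schedule
        draws = np.array([
            simulate_survival(truth, _const_state(times), seed=1000 + s)
            for s in range(800)
        ])
        km = KaplanMeierFitter().fit(draws[:, 0], event_observed=1 - draws[:, 1])
        assert km.median_survival_time_ == pytest.approx(np.log(2) / h, rel=0.15)

    def test_doubling_damage_loading_shortens_life(self):
        times = np.arange(0.0, 12.0, 1.0)
        meds = []
        for gd in (0.5, 1.0):
            truth = flat_truth(
                base_hazard_male=np.full(3, 0.05),
                base_hazard_female=np.full(3, 0.05),
                gamma_d=gd, schedule=times,
            )
            # positive link-scale damage rate so the loading acts upward
            st = SubjectState(
                times=times, fi=np.full(len(times), 0.2),
                eta_r=np.full(len(times), -2.0), eta_d=np.full(len(times), 1.5),
                eta_r_slope=np.zeros(len(times) - 1),
                eta_d_slope=np.zeros(len(times) - 1),
                sex=0.0, treatment=0.0, baseline_age=16.0,
            )
            d = np.array([simulate_survival(truth, st, seed=s)[0] for s in range(600)])
            meds.append(np.median(d))
        assert meds[1] < meds[0]


class TestHumanCohort:
    def test_determinism_and_no_mortality(self):
        a = simulate_human_cohort(HumanGroundTruth(), 12, seed=3)
        b = simulate_human_cohort(HumanGroundTruth(), 12, seed=3)
        pd.testing.assert_frame_equal(a.panel.observations, b.panel.observations)
        assert a.panel.survival is None

    def test_ground_truth_yaml_round_trip(self, tmp_path):
        t = GroundTruth()
        t.to_yaml(tmp_path / "t.yaml")
        t2 = GroundTruth.from_yaml(tmp_path / "t.yaml")
        assert np.allclose(t.beta_r, t2.beta_r)
        assert np.allclose(t.re_corr, t2.re_corr)
        assert np.allclose(t.schedule, t2.schedule)
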