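"""Pre-processing rules: imputation, fractional expansion, visit filters,
cohort selection, and sensitivity pruning."""

import numpy as np
import pandas as pd
import pytest

from frailtydynamics.panel import DeficitPanel
from frailtydynamics.preprocess import (
    EncodingError,
    ImputationError,
    elsa_select,
    encode_fractional,
    expand_fractional_panel,
    filter_visits,
    impute_locf,
    prune_isolated_transitions,
)


def make_panel(series_by_deficit, times=None, covariates=None, **cov):
    """Panel for one subject from {deficit_id: value list}."""
    any_series = next(iter(series_by_deficit.values()))
    times = np.arange(len(any_series), dtype=float) if times is None else times
    rows = []
    for did, vals in series_by_deficit.items():
        for t, v in zip(times, vals):
            rows.append({"subject_id": "s0", "time": t, "deficit_id": did, "value": v})
    cov = cov or {"sex": 0.0}
    covariates = pd.DataFrame([{"subject_id": "s0", **cov}]).set_index("subject_id")
    return DeficitPanel(pd.DataFrame(rows), covariates)


class TestLocf:
    @pytest.mark.parametrize("series,expected", [
        ([0, np.nan, 1], [0, 0, 1]),            # forward fill
        ([np.nan, 1, np.nan], [1, 1, 1]),        # backward then forward
        ([0, 1, 0], [0, 1, 0]),                  # identity when complete
    ])
    def test_fill(self, series, expected):
        out = impute_locf(make_panel({"d0": series}))
        assert out.observations["value"].tolist() == expected

    def test_fully_missing_series_errors(self):
        with pytest.raises(ImputationError, match="d0"):
            impute_locf(make_panel({"d0": [np.nan, np.nan]}))


class TestFractionalEncoding:
    @pytest.mark.parametrize("value,bits", [
        (0.75, [1, 1, 1, 0]),
        (0.0, [0, 0, 0, 0]),
        (0.5, [1, 1, 0, 0]),
        (1.0, [1, 1, 1, 1]),
    ])
    def test_encode(self, value, bits):
        assert encode_fractional(value).tolist() == bits

    def test_off_grid_errors(self):
        with pytest.raises(EncodingError):
            encode_fractional(0.3)

    def test_expansion_preserves_fi_exactly(self, rng):
        grid = np.array([0, 0.25, 0.5, 0.75, 1.0])
        vals = rng.choice(grid, size=(4, 31))
        panel = make_panel(
            {f"d{k}": vals[:, k] for k in range(31)}
        )
        out = expand_fractional_panel(panel)
        assert out.n_items == 124
        fi_before = panel.fi().set_index("time")["fi"]
        fi_after = out.fi().set_index("time")["fi"]
        assert (fi_before == fi_after).all()  # bit-exact


class TestVisitFilters:
    def test_min_gap_removes_close_visit(self):
        p = make_panel({"d0": [0, 0, 1]}, times=np.array([0.0, 0.05, 1.0]))
        out = filter_visits(p, min_gap=0.1)
        assert sorted(out.observations["time"].unique()) == [0.0, 1.0]

    def test_max_gap_removes_late_visit_but_keeps_subject(self):
        p = make_panel({"d0": [0, 0, 1]}, times=np.array([21.0, 22.0, 25.0]))
        out = filter_visits(p, max_gap=2.0)
        assert sorted(out.observations["time"].unique()) == [21.0, 22.0]
        assert len(out.subjects) == 1

    def test_single_visit_subject_removed(self):
        p = make_panel({"d0": [0]}, times=np.array([5.0]))
        out = filter_visits(p)
        assert len(out.subjects) == 0

    def test_order_stable(self):
        p = make_panel({"d0": [0, 1, 0, 1]}, times=np.array([0.0, 1.0, 2.0, 3.0]))
        out = filter_visits(p, min_gap=0.0)
        assert out.observations["time"].is_monotonic_increasing


def human_panel(n_visits, baseline_age=60.0, wealth=100.0, imputed=False, gap=2.0):
    times = np.arange(n_visits) * gap
    rows = [
        {"subject_id": "h0", "time": t, "deficit_id": "d0", "value": 0.0}
        for t in times
    ]
    cov = pd.DataFrame([{
        "subject_id": "h0", "sex": 0.0, "baseline_age": baseline_age,
        "wealth": wealth, "wealth_imputed": imputed,
    }]).set_index("subject_id")
    return DeficitPanel(pd.DataFrame(rows), cov, time_unit="years")


class TestElsaSelect:
    def test_five_visits_dropped_six_kept(self):
        assert len(elsa_select(human_panel(5)).subjects) == 0
        assert len(elsa_select(human_panel(6)).subjects) == 1

    @pytest.mark.parametrize("age,kept", [(49.5, 0), (50.0, 1), (89.0, 1), (89.5, 0)])
    def test_baseline_age_window(self, age, kept):
        assert len(elsa_select(human_panel(6, baseline_age=age)).subjects) == kept

    def test_gap_above_four_years_dropped(self):
        p = human_panel(6, gap=4.5)
        assert len(elsa_select(p).subjects) == 0

    def test_imputed_wealth_dropped(self):
        assert len(elsa_select(human_panel(6, imputed=True)).subjects) == 0

    def test_wealth_transform_identical_raw(self):
        # w_raw = c for everyone -> w = log(2c)
        out = elsa_select(human_panel(6, wealth=50.0))
        assert out.covariates["wealth"].iloc[0] == pytest.approx(np.log(100.0))


class TestPruning:
    @pytest.mark.parametrize("series,expected", [
        ([0, 0, 1, 0, 0], [0, 0, 0, 0, 0]),  # erroneous damage
        ([1, 1, 0, 1, 1], [1, 1, 1, 1, 1]),  # erroneous repair
        ([0, 1, 0], [0, 1, 0]),              # needs 2 flanking visits
        ([0, 0, 1, 1, 0, 0], [0, 0, 1, 1, 0, 0]),  # length-2 excursions kept
    ])
    def test_patterns(self, series, expected):
        out = prune_isolated_transitions(make_panel({"d0": series}))
        assert out.observations["value"].tolist() == [float(v) for v in expected]

    def test_idempotent_and_never_adds_transitions(self, rng):
        from frailtydynamics.transitions import count_transitions

        series = rng.integers(0, 2, size=(20, 5)).astype(float)
        panel = make_panel({f"d{k}": series[:, k] for k in range(5)})
        once = prune_isolated_transitions(panel)
        twice = prune_isolated_transitions(once)
        pd.testing.assert_frame_equal(once.observations, twice.observations)
        n_before = count_transitions(panel).data[["n_damage", "n_repair"]].sum().sum()
        n_after = count_transitions(once).data[["n_damage", "n_repair"]].sum().sum()
        assert n_after <= n_before
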