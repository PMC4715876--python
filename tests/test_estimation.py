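"""Transition estimation: LOCF, empirical counting, proportional-odds fit."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from adhd_cea.estimation import (
    EstimationError,
    empirical_transition_matrix,
    fit_ordered_logit,
    locf_impute,
    logit_to_matrix,
    proportional_odds_matrix,
    read_panel,
    transition_pairs,
    write_panel,
)
from adhd_cea.synthetic import PanelSimSpec, simulate_panel

BASE_INIT = np.array([0.0, 0.0352, 0.9055, 0.0593])


def panel_from_paths(paths):
    """Build a panel DataFrame from lists of CGI-S values (None = missing)."""
    rows = []
    for pid, path in enumerate(paths):
        for week, cgis in enumerate(path):
            rows.append({"patient_id": f"P{pid}", "arm": "comparator", "week": week, "cgis": cgis})
    panel = pd.DataFrame(rows)
    panel["cgis"] = panel["cgis"].astype("Int64")
    return panel


class TestLocf:
    def test_fills_gap_from_post_baseline_value(self):
        panel = locf_impute(panel_from_paths([[5, 4, None, 3]]))
        assert panel["cgis"].tolist() == [5, 4, 4, 3]

    def test_baseline_never_carried_forward(self):
        panel = locf_impute(panel_from_paths([[5, None, 4]]))
        vals = panel["cgis"].tolist()
        assert vals[0] == 5 and pd.isna(vals[1]) and vals[2] == 4

    def test_fully_observed_panel_unchanged(self):
        original = panel_from_paths([[5, 4, 4, 3], [6, 6, 5, 5]])
        filled = locf_impute(original)
        pd.testing.assert_frame_equal(
            filled.reset_index(drop=True), original.reset_index(drop=True)
        )

    def test_observed_values_never_altered(self):
        original = panel_from_paths([[5, None, 4, None, 2]])
        filled = locf_impute(original)
        observed = original["cgis"].notna()
        assert (filled.loc[observed, "cgis"] == original.loc[observed, "cgis"]).all()

    def test_carries_across_multiple_gaps(self):
        panel = locf_impute(panel_from_paths([[5, 4, None, None, None]]))
        assert panel["cgis"].tolist() == [5, 4, 4, 4, 4]


class TestEmpirical:
    def test_single_constant_path(self):
        tm = empirical_transition_matrix(panel_from_paths([[1, 1, 1]]))
        np.testing.assert_allclose(tm.p[0], [1, 0, 0, 0])

    def test_counting_two_transitions_from_mild(self):
        # Mild(2) -> Mild(3) and Mild(3) -> Moderate(4)
        tm = empirical_transition_matrix(panel_from_paths([[2, 3, 4]]))
        np.testing.assert_allclose(tm.p[1], [0, 0.5, 0.5, 0])
        assert tm.se[1, 1] == pytest.approx(np.sqrt(0.25 / 2))

    def test_missing_pairs_are_skipped(self):
        pairs = transition_pairs(panel_from_paths([[4, None, 4, 4]]))
        assert pairs.sum() == 1  # only the week2 -> week3 pair is complete

    def test_baseline_pair_toggle(self):
        panel = panel_from_paths([[4, 4, 4]])
        assert transition_pairs(panel, include_baseline=True).sum() == 2
        assert transition_pairs(panel, include_baseline=False).sum() == 1

    def test_empty_origin_rows_flagged_nan(self):
        with pytest.warns(UserWarning, match="no observed transitions"):
            tm = empirical_transition_matrix(panel_from_paths([[4, 4, 4]]))
        assert np.isnan(tm.p[0]).all() and np.isnan(tm.p[3]).all()

    def test_recovers_generator_within_binomial_error(self, base_config):
        P = base_config.comparator.transitions.p
        spec = PanelSimSpec(
            transition_matrix=P, initial_distribution=BASE_INIT, n_patients=500, seed=20240101
        )
        tm = empirical_transition_matrix(simulate_panel(spec))
        counts = transition_pairs(simulate_panel(spec))
        n_row = counts.sum(axis=1, keepdims=True)
        se = np.sqrt(np.clip(P * (1 - P), 1e-12, None) / np.clip(n_row, 1, None))
        observed = n_row[:, 0] > 30  # skip rarely visited origins
        assert np.all(np.abs(tm.p[observed] - P[observed]) <= 3 * se[observed] + 1e-9)


class TestOrderedLogit:
    def test_closed_form_rows_at_zero_beta(self):
        p = proportional_odds_matrix(np.array([-1.0, 0.0, 1.0]), np.zeros(3))
        expected = [expit(-1), expit(0) - expit(-1), expit(1) - expit(0), 1 - expit(1)]
        for row in p:
            np.testing.assert_allclose(row, expected, atol=1e-12)

    def test_rows_sum_to_one_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            theta = np.sort(rng.normal(size=3) * 3)
            theta += np.arange(3) * 1e-3  # ensure strict ordering
            p = proportional_odds_matrix(theta, rng.normal(size=3) * 2)
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-15)

    def test_nonincreasing_thresholds_rejected(self):
        with pytest.raises(ValueError):
            proportional_odds_matrix(np.array([1.0, 0.5, 2.0]), np.zeros(3))

    def test_parameter_recovery_within_3se(self):
        theta = np.array([-1.0, 0.5, 2.0])
        beta = np.array([1.0, 2.5, 4.0])
        gen = proportional_odds_matrix(theta, beta)
        spec = PanelSimSpec(
            transition_matrix=gen,
            initial_distribution=np.full(4, 0.25),
            n_patients=1000,
            seed=11,
        )
        fit = fit_ordered_logit(simulate_panel(spec))
        se = np.sqrt(np.diag(fit.cov))
        est = np.concatenate([fit.beta, fit.theta])
        true = np.concatenate([beta, theta])
        assert np.all(np.abs(est - true) <= 3 * se)

    def test_matrix_round_trip_recovery(self):
        theta = np.array([-1.0, 0.5, 2.0])
        beta = np.array([0.8, 2.0, 3.5])
        gen = proportional_odds_matrix(theta, beta)
        spec = PanelSimSpec(
            transition_matrix=gen, initial_distribution=np.full(4, 0.25), n_patients=1000, seed=5
        )
        tm = logit_to_matrix(fit_ordered_logit(simulate_panel(spec)))
        assert np.abs(tm.p - gen).max() < 0.05
        np.testing.assert_allclose(tm.p.sum(axis=1), 1.0, atol=1e-12)

    def test_independence_gives_near_zero_beta(self):
        # next state independent of previous state
        P = np.tile(np.array([0.1, 0.4, 0.4, 0.1]), (4, 1))
        spec = PanelSimSpec(
            transition_matrix=P, initial_distribution=np.full(4, 0.25), n_patients=1500, seed=3
        )
        fit = fit_ordered_logit(simulate_panel(spec))
        se = np.sqrt(np.diag(fit.cov))[:3]
        assert np.all(np.abs(fit.beta) <= 3 * se)

    def test_insufficient_origin_variation_rejected(self):
        with pytest.raises(EstimationError, match="previous states"):
            fit_ordered_logit(panel_from_paths([[1, 1, 1], [1, 1, 1]]))

    def test_estimation_error_shrinks_with_panel_size(self, base_config):
        P = base_config.comparator.transitions.p
        errs = []
        for n in (200, 2000):
            spec = PanelSimSpec(
                transition_matrix=P, initial_distribution=np.full(4, 0.25), n_patients=n, seed=77
            )
            tm = logit_to_matrix(fit_ordered_logit(simulate_panel(spec)))
            errs.append(np.abs(tm.p - P).max())
        assert errs[1] < errs[0]

    def test_agrees_with_statsmodels_ordered_model(self):
        # independent reference fit of the same proportional-odds likelihood
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        gen = proportional_odds_matrix(np.array([-0.5, 0.8, 2.2]), np.array([0.9, 1.8, 3.0]))
        spec = PanelSimSpec(
            transition_matrix=gen, initial_distribution=np.full(4, 0.25), n_patients=400, seed=13
        )
        panel = simulate_panel(spec)
        fit = fit_ordered_logit(panel)

        pairs = []
        for _, grp in panel.sort_values(["patient_id", "week"]).groupby("patient_id"):
            states = np.select(
                [grp["cgis"] == 1, grp["cgis"] <= 3, grp["cgis"] <= 5, grp["cgis"] <= 7],
                [0, 1, 2, 3],
            )
            for a in range(len(states) - 1):
                pairs.append((states[a], states[a + 1]))
        prev = np.array([p for p, _ in pairs])
        cur = np.array([c for _, c in pairs])
        X = np.column_stack([(prev == k).astype(float) for k in (1, 2, 3)])
        sm_fit = OrderedModel(cur, X, distr="logit").fit(method="bfgs", disp=False)
        np.testing.assert_allclose(sm_fit.params[:3], fit.beta, atol=5e-3)


class TestPanelIO:
    def test_csv_round_trip_preserves_missing(self, tmp_path):
        panel = panel_from_paths([[5, None, 4], [6, 6, None]])
        path = tmp_path / "panel.csv"
        write_panel(panel, path)
        back = read_panel(path)
        assert back["cgis"].isna().sum() == 2
        pd.testing.assert_series_equal(
            back["cgis"].reset_index(drop=True), panel["cgis"].reset_index(drop=True)
        )
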