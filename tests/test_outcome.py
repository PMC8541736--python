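"""Logistic outcome model, ROC/AUC, elimination, win-lose history test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from risetrack.outcome import (
    backward_eliminate,
    bootstrap_auc_sd,
    cumulative_counts,
    fit_logistic_glm,
    roc_auc,
    time_resolved_auc,
    winlose_autocorrelation_test,
)


class TestRocAuc:
    def test_hand_example(self):
        # winners {2, 4}, losers {3, 1}: 3 of 4 pairs correctly ordered
        scores = np.array([2.0, 4.0, 3.0, 1.0])
        labels = np.array([True, True, False, False])
        assert roc_auc(scores, labels) == 0.75

    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_fully_tied_scores(self):
        assert roc_auc([5, 5, 5, 5], [1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        for _ in range(20):
            s = np.round(rng.normal(size=30), 1)
            y = rng.random(30) < 0.4
            if y.all() or not y.any():
                continue
            assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_complement_symmetry(self, data):
        n = data.draw(st.integers(4, 16))
        scores = data.draw(
            st.lists(st.integers(0, 5), min_size=n, max_size=n).map(np.array)
        )
        labels = np.arange(n) < n // 2
        assert roc_auc(scores, labels) == pytest.approx(
            1.0 - roc_auc(scores, ~labels), abs=1e-12
        )


class TestBootstrap:
    def test_separated_data_sd_zero(self):
        sd = bootstrap_auc_sd([1, 2, 3, 10, 11], [0, 0, 0, 1, 1], n_boot=200, seed=0)
        assert sd == 0.0

    def test_seed_reproducible(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=40)
        y = np.arange(40) < 20
        assert bootstrap_auc_sd(s, y, seed=5) == bootstrap_auc_sd(s, y, seed=5)

    def test_two_point_toy_matches_enumeration(self):
        # one observation per class: every stratified replicate resamples the
        # same points, AUC is constant, SD must be exactly 0
        assert bootstrap_auc_sd([0.2, 0.9], [0, 1], n_boot=100, seed=2) == 0.0
        # two per class: enumerate the 16 equiprobable replicates
        pos, neg = np.array([4.0, 2.0]), np.array([3.0, 1.0])
        aucs = []
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    for m in range(2):
                        s = np.array([pos[i], pos[j], neg[k], neg[m]])
                        aucs.append(roc_auc(s, [1, 1, 0, 0]))
        exact_sd = np.std(aucs, ddof=1)
        est = bootstrap_auc_sd([4.0, 2.0, 3.0, 1.0], [1, 1, 0, 0],
                               n_boot=4000, seed=3)
        assert est == pytest.approx(exact_sd, abs=0.03)


class TestLogisticGlm:
    def test_single_binary_feature_matches_2x2_log_odds(self):
        x = np.repeat([0, 1], 40)
        rng = np.random.default_rng(4)
        y = np.where(x == 1, rng.random(80) < 0.75, rng.random(80) < 0.35)
        fit = fit_logistic_glm(pd.DataFrame({"x": x}), y)
        n11 = np.sum(y[x == 1]); n10 = np.sum(~y[x == 1])
        n01 = np.sum(y[x == 0]); n00 = np.sum(~y[x == 0])
        assert fit.params["x"] == pytest.approx(
            np.log(n11 * n00 / (n10 * n01)), rel=1e-6
        )

    def test_degenerate_outcome_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_logistic_glm(pd.DataFrame({"x": [1.0, 2.0]}), [1, 1])

    def test_perfect_separation_flagged_not_silent(self):
        x = np.linspace(-2, 2, 30)
        y = x > 0
        fit = fit_logistic_glm(pd.DataFrame({"x": x}), y)
        assert fit.separation_flag

    def test_null_feature_ci_covers_zero(self):
        rng = np.random.default_rng(5)
        covered = 0
        for rep in range(30):
            x = rng.normal(size=300)
            y = rng.random(300) < 0.5
            fit = fit_logistic_glm(pd.DataFrame({"x": x}), y)
            ci = fit.conf_int()
            covered += ci.loc["x", "lo"] <= 0.0 <= ci.loc["x", "hi"]
        assert covered >= 27  # ~95% nominal coverage


class TestTimeResolvedAuc:
    def test_all_zero_at_t0_gives_half(self):
        et = np.array([0.0, 60.0])
        lc = cumulative_counts([np.array([30.0])] * 5, et)
        wc = cumulative_counts([np.array([50.0])] * 5, et)
        auc = time_resolved_auc(lc, wc, et)
        assert auc[0] == 0.5

    def test_decreasing_counts_rejected(self):
        et = np.array([0.0, 60.0])
        bad = np.array([[2.0, 1.0]])
        with pytest.raises(ValueError):
            time_resolved_auc(bad, np.array([[0.0, 1.0]]), et)

    def test_separated_rates_reach_high_auc(self):
        from risetrack.synthetic import poisson_times

        rng = np.random.default_rng(6)
        et = np.arange(0.0, 1801.0, 60.0)
        lc = cumulative_counts(
            [poisson_times(184 / 10800, 10800, rng) for _ in range(20)], et
        )
        wc = cumulative_counts(
            [poisson_times(18 / 10800, 10800, rng) for _ in range(20)], et
        )
        auc = time_resolved_auc(lc, wc, et)
        assert auc[-1] > 0.95


class TestBackwardElimination:
    def test_alpha_one_keeps_all_alpha_zero_drops_all(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        y = rng.normal(size=100)
        assert len(backward_eliminate(X, y, alpha=1.0).final_features) == 3
        assert backward_eliminate(X, y, alpha=0.0).final_features == []

    def test_single_feature_below_alpha_retained(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        res = backward_eliminate(pd.DataFrame({"x": x}), y)
        assert res.final_features == ["x"]
        assert res.r_squared is not None

    def test_collinear_feature_dropped_with_warning(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=100)
        X = pd.DataFrame({"x": x, "x2": 2.0 * x})
        with pytest.warns(UserWarning, match="collinear"):
            res = backward_eliminate(X, rng.normal(size=100), alpha=1.0)
        assert res.final_features == ["x"]

    def test_elimination_trace_is_ordered_by_removal(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(150, 3)), columns=list("abc"))
        y = 1.0 * X["a"] + rng.normal(size=150)
        res = backward_eliminate(X, y)
        assert "a" in res.final_features
        removed = [name for name, _ in res.eliminated]
        assert set(removed) <= {"b", "c"}


class TestWinLoseHistory:
    def test_alternating_sequences_are_extreme(self):
        seqs = [np.tile([1.0, -1.0], 5) for _ in range(8)]
        _, p = winlose_autocorrelation_test(seqs, seed=0)
        assert p <= 0.01

    def test_iid_sequences_calibrated(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_runs = 60
        for run in range(n_runs):
            seqs = [rng.choice([-1.0, 1.0], 10) for _ in range(6)]
            try:
                _, p = winlose_autocorrelation_test(seqs, n_perm=400, seed=run)
            except ValueError:
                continue
            rejections += p <= 0.05
        assert rejections / n_runs < 0.15

    def test_constant_sequences_excluded_error_when_none_left(self):
        with pytest.raises(ValueError, match="no usable"):
            winlose_autocorrelation_test([np.ones(10)], seed=1)

    def test_short_sequences_rejected(self):
        with pytest.raises(ValueError):
            winlose_autocorrelation_test([np.array([1.0, -1.0])], seed=1)
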