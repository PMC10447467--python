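"""Survival and classification statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmesurv import evaluate as ev


# ---------------------------------------------------------------------------
# brute-force oracles (kept deliberately naive and independent)
# ---------------------------------------------------------------------------

def km_oracle(times, events, t):
    """Product over event times <= t of (1 - d/n)."""
    s = 1.0
    for u in sorted(set(times[events.astype(bool)])):
        if u > t:
            break
        n_at_risk = np.sum(times >= u)
        d = np.sum((times == u) & events.astype(bool))
        s *= 1.0 - d / n_at_risk
    return s


def cindex_oracle(risk, times, events):
    """Harrell's C by exhaustive pair enumeration. Comparable pairs: the
    earlier time is an event, or the times tie and exactly one is an event
    (the censored subject is known to survive longer)."""
    conc = ties = comp = 0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            comparable = (times[i] < times[j] and events[i]) or \
                (times[i] == times[j] and events[i] and not events[j])
            if not comparable:
                continue
            comp += 1
            if risk[i] > risk[j]:
                conc += 1
            elif risk[i] == risk[j]:
                ties += 1
    return (conc + 0.5 * ties) / comp


def auc_oracle(scores, labels):
    pos = scores[labels]
    neg = scores[~labels]
    u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return u / (len(pos) * len(neg))


def random_records(rng, n=None, censoring=True):
    n = n or int(rng.integers(5, 25))
    times = rng.choice(np.arange(1.0, 15.0), size=n)
    events = rng.integers(0, 2, size=n) if censoring else np.ones(n, int)
    if events.sum() == 0:
        events[rng.integers(n)] = 1
    return times, events.astype(bool)


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        km = ev.km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.survival_at(3.0) == 1.0

    def test_hand_computed_product_limit(self):
        km = ev.km_estimate([1.0, 2.0, 3.0], [1, 1, 0])
        assert km.survival_at(2.0) == pytest.approx((2 / 3) * (1 / 2))

    def test_matches_brute_force_product_on_random_data(self, rng):
        for _ in range(100):
            times, events = random_records(rng)
            km = ev.km_estimate(times, events)
            for t in (1.0, 4.0, 9.0, 14.0):
                assert km.survival_at(t) == pytest.approx(
                    km_oracle(times, events, t), abs=1e-12)

    def test_greenwood_variance_is_zero_before_first_event(self):
        km = ev.km_estimate([5.0, 6.0], [1, 0])
        assert km.variance[0] >= 0


class TestLogRank:
    def test_identical_groups_give_null_statistic(self):
        times = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        events = np.array([1, 0, 1, 1] * 2)
        groups = np.repeat([0, 1], 4)
        stat, p = ev.log_rank_test(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_textbook_two_group_statistic(self):
        """O-E/V computed by hand for a tiny two-group dataset."""
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 1, 1, 1, 1])
        groups = np.array([0, 1, 0, 1, 0, 1])
        # hand computation of sum(O-E) and sum(V) over event times
        o_minus_e, v = 0.0, 0.0
        for t in times:
            at_risk = times >= t
            n = at_risk.sum()
            n1 = (at_risk & (groups == 1)).sum()
            d = 1
            e1 = d * n1 / n
            o1 = int(groups[np.where(times == t)[0][0]] == 1)
            o_minus_e += o1 - e1
            if n > 1:
                v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected = o_minus_e ** 2 / v
        stat, _ = ev.log_rank_test(times, events, groups)
        assert stat == pytest.approx(expected, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            ev.log_rank_test([1.0, 2.0], [1, 1], [0, 0])


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

class TestCox:
    def test_null_covariate_ci_covers_one(self, rng):
        n = 300
        df = pd.DataFrame({
            "time": rng.exponential(10, n) + 0.01,
            "event": rng.integers(0, 2, n),
            "x": rng.normal(size=n)})
        fit = ev.cox_fit(df, ["x"])
        assert fit.summary.loc["x", "hr_lower"] < 1 < fit.summary.loc["x", "hr_upper"]

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1], "x": [1.0, 1.0]})
        with pytest.raises(ValueError):
            ev.cox_fit(df, ["x"])

    def test_score_test_equivalence_with_log_rank(self, rng):
        """For a binary covariate without ties, the log-rank statistic equals
        the Cox score test at beta = 0 (classic equivalence)."""
        n = 40
        times = rng.permutation(np.arange(1.0, n + 1.0))  # no ties
        events = np.ones(n, dtype=int)
        group = rng.integers(0, 2, size=n)
        stat, _ = ev.log_rank_test(times, events, group)
        # score statistic: U(0)^2 / I(0) with Breslow risk sets
        u = 0.0
        info = 0.0
        for i in range(n):
            at_risk = times >= times[i]
            pbar = group[at_risk].mean()
            u += group[i] - pbar
            info += pbar * (1 - pbar)
        assert stat == pytest.approx(u ** 2 / info, abs=1e-6)

    def test_recovers_known_hazard_ratio(self, rng):
        n = 1000
        x = rng.integers(0, 2, size=n)
        times = rng.exponential(1.0 / (0.05 * np.exp(np.log(2) * x)))
        cens = rng.uniform(0, 40, size=n)
        df = pd.DataFrame({"time": np.minimum(times, cens) + 1e-9,
                           "event": (times <= cens).astype(int), "x": x})
        fit = ev.cox_fit(df, ["x"])
        lo, hi = fit.summary.loc["x", ["hr_lower", "hr_upper"]]
        assert lo < 2.0 < hi


# ---------------------------------------------------------------------------
# time-dependent ROC / DeLong / C-index
# ---------------------------------------------------------------------------

class TestTimeDependentROC:
    def test_perfect_risk_ordering_gives_auc_one(self):
        times = np.arange(1.0, 11.0)
        events = np.ones(10, int)
        risk = -times  # earlier event = higher risk
        roc = ev.time_dependent_roc(risk, times, events, horizon=5.0)
        assert roc["auc"] == pytest.approx(1.0, abs=1e-10)

    def test_uninformative_risk_auc_near_half(self, rng):
        n = 400
        times = rng.exponential(10, n) + 0.01
        events = np.ones(n, int)
        risk = rng.normal(size=n)
        roc = ev.time_dependent_roc(risk, times, events, horizon=8.0)
        assert abs(roc["auc"] - 0.5) < 0.08

    def test_reduces_to_binary_auc_without_censoring(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 40))
            times = rng.uniform(1, 20, n)
            events = np.ones(n, int)
            risk = rng.normal(size=n)
            horizon = float(np.median(times))
            labels = times <= horizon
            if labels.all() or not labels.any():
                continue
            roc = ev.time_dependent_roc(risk, times, events, horizon)
            assert roc["auc"] == pytest.approx(auc_oracle(risk, labels), abs=1e-10)

    def test_no_events_before_horizon_rejected(self):
        with pytest.raises(ValueError):
            ev.time_dependent_roc([1.0, 2.0], [5.0, 6.0], [1, 1], horizon=2.0)


class TestDeLong:
    def test_identical_scores_give_zero_difference(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50).astype(bool)
        labels[:2] = [True, False]
        res = ev.delong_compare(scores, scores, labels)
        assert res["delta_auc"] == 0.0
        assert res["p"] == 1.0

    def test_placement_auc_equals_mann_whitney(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 30))
            scores = rng.normal(size=n)
            labels = rng.integers(0, 2, size=n).astype(bool)
            if labels.all() or not labels.any():
                continue
            assert ev.delong_auc(scores, labels) == pytest.approx(
                auc_oracle(scores, labels), abs=1e-12)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            ev.delong_compare([1.0, 2.0], [2.0, 1.0], [True, True])


class TestConcordance:
    def test_perfect_ordering_gives_one(self):
        times = np.arange(1.0, 8.0)
        assert ev.concordance_index(-times, times, np.ones(7)) == 1.0

    def test_random_risk_near_half(self, rng):
        n = 500
        times = rng.exponential(5, n) + 0.01
        assert abs(ev.concordance_index(rng.normal(size=n), times,
                                        np.ones(n)) - 0.5) < 0.06

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(100):
            times, events = random_records(rng, n=15)
            risk = rng.normal(size=15)
            assert ev.concordance_index(risk, times, events) == pytest.approx(
                cindex_oracle(risk, times, events), abs=1e-12)


# ---------------------------------------------------------------------------
# NRI
# ---------------------------------------------------------------------------

class TestNRI:
    def test_identical_models_give_zero(self, rng):
        times, events = random_records(rng, n=60)
        s = rng.normal(size=60)
        res = ev.nri_timepoint(s, s, times, events, horizon=7.0, n_boot=20, rng=1)
        assert res["nri"] == 0.0

    def test_antisymmetry(self, rng):
        times, events = random_records(rng, n=80)
        a, b = rng.normal(size=80), rng.normal(size=80)
        x = ev.nri_timepoint(a, b, times, events, 7.0, n_boot=10, rng=1)["nri"]
        y = ev.nri_timepoint(b, a, times, events, 7.0, n_boot=10, rng=1)["nri"]
        assert x == pytest.approx(-y, abs=1e-12)

    def test_hand_counted_no_censoring_example(self):
        # 4 events by t=5, 4 nonevents; up/down counted by hand:
        times = np.array([1.0, 2.0, 3.0, 4.0, 9.0, 9.0, 9.0, 9.0])
        events = np.ones(8, int)
        old = np.zeros(8)
        new = np.array([1.0, 1.0, -1.0, 1.0, -1.0, -1.0, 1.0, -1.0])
        # events: 3 up, 1 down -> 0.5 ; nonevents: 3 down, 1 up -> 0.5
        res = ev.nri_timepoint(new, old, times, events, horizon=5.0,
                               n_boot=10, rng=0)
        assert res["nri"] == pytest.approx(1.0, abs=1e-12)

    def test_true_signal_added_yields_positive_nri(self, rng):
        n = 400
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        lam = 0.05 * np.exp(0.8 * x + 0.8 * z)
        t_event = rng.exponential(1 / lam)
        cens = rng.uniform(0, 40, n)
        times = np.minimum(t_event, cens) + 1e-9
        events = (t_event <= cens).astype(int)
        res = ev.nri_timepoint(x + z, x, times, events, horizon=10.0,
                               n_boot=20, rng=2)
        assert res["nri"] > 0


# ---------------------------------------------------------------------------
# Brier / IBS / .632+ / calibration
# ---------------------------------------------------------------------------

class TestBrier:
    def test_oracle_predictions_without_censoring_score_zero(self):
        times = np.array([1.0, 2.0, 10.0, 11.0])
        events = np.ones(4, int)
        grid = np.array([5.0])
        surv = (times[:, None] > grid[None, :]).astype(float)
        bs, ibs = ev.brier_and_ibs(surv, times, events, grid)
        assert bs[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_half_prediction_scores_quarter(self):
        times = np.array([1.0, 2.0, 10.0, 11.0])
        events = np.ones(4, int)
        grid = np.array([5.0])
        bs, _ = ev.brier_and_ibs(np.full((4, 1), 0.5), times, events, grid)
        assert bs[0] == pytest.approx(0.25, abs=1e-12)

    def test_reduces_to_mse_without_censoring(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 30))
            times = rng.uniform(1, 20, n)
            events = np.ones(n, int)
            grid = np.array([float(np.median(times))])
            surv = rng.uniform(0, 1, size=(n, 1))
            bs, _ = ev.brier_and_ibs(surv, times, events, grid)
            mse = np.mean(((times > grid[0]).astype(float) - surv[:, 0]) ** 2)
            assert bs[0] == pytest.approx(mse, abs=1e-12)

    def test_grid_outside_follow_up_rejected(self):
        with pytest.raises(ValueError):
            ev.brier_and_ibs(np.full((2, 1), 0.5), [1.0, 2.0], [1, 1], [5.0])


class TestPredictionError632:
    @staticmethod
    def km_model(grid):
        def fit(df_train):
            km = ev.km_estimate(df_train["time"], df_train["event"])
            base = np.array([km.survival_at(t) for t in grid])

            def predictor(df_test):
                return np.tile(base, (len(df_test), 1))
            return predictor
        return fit

    def test_bounded_curves(self, outcome_cohort):
        df = outcome_cohort.iloc[:150].reset_index(drop=True)
        grid = np.array([6.0, 12.0, 24.0])
        res = ev.prediction_error_632plus(
            {"km": self.km_model(grid)}, df, grid, B=10, rng=0)
        assert np.all(res["km"]["err632plus"] >= 0)
        assert np.all(res["km"]["err632plus"] <= 1)

    def test_informative_model_beats_null_model(self, outcome_cohort):
        df = outcome_cohort.iloc[:250].reset_index(drop=True)
        grid = np.array([6.0, 12.0, 24.0])

        def cox_model(df_train):
            fit = ev.cox_fit(df_train, ["true_class"])
            km = ev.km_estimate(df_train["time"], df_train["event"])
            base = np.array([km.survival_at(t) for t in grid])
            lp0 = fit.linear_predictor(df_train).mean()

            def predictor(df_test):
                lp = fit.linear_predictor(df_test) - lp0
                return np.clip(base[None, :], 1e-12, 1) ** np.exp(lp)[:, None]
            return predictor

        res = ev.prediction_error_632plus(
            {"null": self.km_model(grid), "class": cox_model}, df, grid,
            B=15, rng=1)
        assert res["class"]["ibs"] < res["null"]["ibs"]


class TestCalibration:
    def test_bins_partition_subjects(self, outcome_cohort):
        df = outcome_cohort.iloc[:200]
        pred = np.random.default_rng(0).uniform(0.1, 0.9, len(df))
        cal = ev.calibration_curve(pred, df["time"], df["event"], 24.0, bins=4)
        assert cal["n"].sum() == len(df)

    def test_constant_prediction_collapses_to_single_bin(self, outcome_cohort):
        df = outcome_cohort.iloc[:100]
        cal = ev.calibration_curve(np.full(len(df), 0.5), df["time"],
                                   df["event"], 24.0, bins=4)
        assert len(cal) == 1
        km = ev.km_estimate(df["time"], df["event"])
        assert cal.loc[0, "observed_km"] == pytest.approx(km.survival_at(24.0))

    def test_oracle_predictions_sit_on_diagonal(self, rng):
        n = 2000
        lam = 0.03 * np.exp(rng.normal(0, 0.8, n))
        t_event = rng.exponential(1 / lam)
        times = np.minimum(t_event, 60.0)
        events = (t_event <= 60.0).astype(int)
        pred = np.exp(-lam * 24.0)  # true P(T > 24)
        cal = ev.calibration_curve(pred, times, events, 24.0, bins=4)
        assert np.all(np.abs(cal["mean_predicted"] - cal["observed_km"]) < 0.08)


# ---------------------------------------------------------------------------
# importance, integrated model, dichotomization
# ---------------------------------------------------------------------------

class TestImportanceAndIntegration:
    def test_single_covariate_has_full_importance(self, outcome_cohort):
        fit = ev.cox_fit(outcome_cohort, ["true_class"])
        imp = ev.chi2_importance(fit)
        assert imp["true_class"] == pytest.approx(1.0)

    def test_importance_proportions_sum_to_one(self, outcome_cohort):
        fit = ev.cox_fit(outcome_cohort, ["true_class", "stage", "age"])
        assert ev.chi2_importance(fit).sum() == pytest.approx(1.0, abs=1e-12)

    def test_equal_effects_share_importance(self, rng):
        n = 3000
        a, b = rng.normal(size=n), rng.normal(size=n)
        lam = 0.05 * np.exp(0.5 * a + 0.5 * b)
        t = rng.exponential(1 / lam)
        df = pd.DataFrame({"time": t + 1e-9, "event": 1, "a": a, "b": b})
        imp = ev.chi2_importance(ev.cox_fit(df, ["a", "b"]))
        assert imp["a"] == pytest.approx(0.5, abs=0.1)

    def test_integrated_model_strata_occupancy_and_freezing(self, outcome_cohort):
        df = outcome_cohort.copy()
        df["dls"] = df["true_class"] + np.random.default_rng(1).normal(0, 0.3, len(df))
        model = ev.integrated_model(df)
        strata = model.strata(df)
        counts = np.bincount(strata, minlength=9)[1:]
        assert counts.sum() == len(df)
        assert counts.max() - counts.min() <= len(df) // 8 + 2
        # applying to a subset must not refit the cutpoints
        sub = df.iloc[:50]
        np.testing.assert_array_equal(model.strata(sub), strata[:50])

    def test_unseen_covariate_level_rejected(self, outcome_cohort):
        df = outcome_cohort.copy()
        df["dls"] = df["true_class"].astype(float)
        model = ev.integrated_model(df)
        bad = df.iloc[:5].copy()
        bad["location"] = 99
        with pytest.raises(ValueError, match="unseen"):
            model.linear_predictor(bad)

    def test_strata_ordered_by_risk(self, outcome_cohort):
        df = outcome_cohort.copy()
        df["dls"] = df["true_class"] + np.random.default_rng(2).normal(0, 0.3, len(df))
        model = ev.integrated_model(df)
        df["stratum"] = model.strata(df)
        lp = model.linear_predictor(df)
        means = [lp[df["stratum"] == s].mean() for s in sorted(df["stratum"].unique())]
        assert all(a < b for a, b in zip(means, means[1:]))


class TestRiskGroups:
    def test_cutoff_is_training_median(self):
        assert ev.median_cutoff([1.0, 2.0, 3.0, 4.0]) == 2.5

    def test_dichotomy_applies_frozen_cutoff(self):
        groups = ev.risk_groups([0.0, 2.5, 5.0], cutoff=2.5)
        assert list(groups) == ["low", "high", "high"]


# ---------------------------------------------------------------------------
# classification report
# ---------------------------------------------------------------------------

class TestClassificationReport:
    def test_perfect_prediction(self):
        truth = np.array([1, 2, 3, 4] * 5)
        rep = ev.classification_report(truth, truth)
        assert rep.accuracy == 1.0
        assert np.all(np.diag(rep.confusion.to_numpy()) == 5)

    def test_toy_two_by_two_rates(self):
        # embed a 2-class problem in the 4-class API: TP=8 FP=2 FN=2 TN=8
        truth = np.array([1] * 10 + [2] * 10)
        pred = np.array([1] * 8 + [2] * 2 + [2] * 8 + [1] * 2)
        rep = ev.classification_report(pred, truth)
        row = rep.per_class.loc[1]
        assert row["sensitivity"] == pytest.approx(0.8)
        assert row["specificity"] == pytest.approx(0.8)
        assert row["ppv"] == pytest.approx(0.8)

    def test_accuracy_ci_matches_closed_form(self, rng):
        truth = rng.integers(1, 5, 200)
        pred = rng.integers(1, 5, 200)
        rep = ev.classification_report(pred, truth)
        p = rep.accuracy
        half = 1.959963984540054 * np.sqrt(p * (1 - p) / 200)
        assert rep.accuracy_ci[1] - p == pytest.approx(min(half, 1 - p), abs=1e-12)

    def test_confusion_sums_to_n(self, rng):
        truth = rng.integers(1, 5, 77)
        pred = rng.integers(1, 5, 77)
        rep = ev.classification_report(pred, truth)
        assert rep.confusion.to_numpy().sum() == 77

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            ev.classification_report([1, 5], [1, 2])
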