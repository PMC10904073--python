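"""Survival statistics against hand-worked and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gemresponse.metrics import UNDEFINED, is_defined
from gemresponse.survival import (
    compare_predicted_groups,
    cox_fit,
    km_median,
    logrank,
    welch_t,
)
from gemresponse.synthetic import (
    SurvivalConfig,
    SyntheticConfig,
    generate_cohort,
    labels_from_cohort,
)

# 6-record fixture with interleaved censoring; the product-limit table is
# worked by hand below:
#   t=2  at-risk 6, 1 death   -> S = 5/6
#   t=3  censored
#   t=5  at-risk 4, 1 death   -> S = 5/6 * 3/4 = 0.625
#   t=7  at-risk 3, 1 death   -> S = 0.625 * 2/3 = 0.41667  (first <= 0.5)
#   t=8  censored
#   t=10 at-risk 1, 1 death   -> S = 0
KM_TIMES = [2.0, 3.0, 5.0, 7.0, 8.0, 10.0]
KM_EVENTS = [1, 0, 1, 1, 0, 1]


class TestWelch:
    def test_identical_groups_give_t_zero_p_one(self):
        t, _, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_matches_satterthwaite_df(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(0, 3, 8)
        t, df, p = welch_t(a, b)
        va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
        df_expected = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        assert df == pytest.approx(df_expected, rel=1e-9)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(1)
        pvals = [welch_t(rng.normal(size=10), rng.normal(size=14))[2] for _ in range(1000)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestKmMedian:
    def test_no_censoring_first_time_curve_at_or_below_half(self):
        # S(1)=0.75, S(2)=0.5 -> median 2
        assert km_median([1, 2, 3, 4], [1, 1, 1, 1]) == 2.0

    def test_all_censored_undefined(self):
        assert km_median([5, 6, 7], [0, 0, 0]) is UNDEFINED

    def test_hand_worked_product_limit_table(self):
        assert km_median(KM_TIMES, KM_EVENTS) == 7.0
        from gemresponse.survival import km_curve

        curve = km_curve(KM_TIMES, KM_EVENTS).set_index("time")["survival"]
        assert curve.loc[2.0] == pytest.approx(5 / 6)
        assert curve.loc[5.0] == pytest.approx(0.625)
        assert curve.loc[7.0] == pytest.approx(5 / 12)
        assert curve.loc[10.0] == pytest.approx(0.0)

    def test_no_censoring_km_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(10, size=25)
        from gemresponse.survival import km_curve

        curve = km_curve(times, np.ones(25, int)).set_index("time")["survival"]
        for t in times:
            assert curve.loc[t] == pytest.approx(np.mean(times > t), abs=1e-12)


def brute_force_logrank(times, events, groups):
    """Textbook O-E log-rank over shared event times (hypergeometric variance)."""
    times, events, groups = map(np.asarray, (times, events, groups))
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2, 1 - stats.chi2.cdf(chi2, df=1)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = list(KM_TIMES) * 2
        events = list(KM_EVENTS) * 2
        groups = [0] * 6 + [1] * 6
        chi2, p = logrank(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_event_table(self):
        rng = np.random.default_rng(3)
        times = np.r_[rng.exponential(5, 15), rng.exponential(12, 15)]
        events = rng.random(30) < 0.8
        groups = np.r_[np.zeros(15, int), np.ones(15, int)]
        chi2, p = logrank(times, events.astype(int), groups)
        chi2_bf, p_bf = brute_force_logrank(times, events.astype(int), groups)
        assert chi2 == pytest.approx(chi2_bf, rel=1e-9)
        assert p == pytest.approx(p_bf, rel=1e-9)

    def test_invariant_to_time_rescaling(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(5, 30)
        events = (rng.random(30) < 0.7).astype(int)
        groups = rng.integers(0, 2, 30)
        if len(np.unique(groups)) < 2:
            groups[0] = 1 - groups[0]
        chi2_a, _ = logrank(times, events, groups)
        chi2_b, _ = logrank(times * 30.44, events, groups)  # days -> months
        assert chi2_a == pytest.approx(chi2_b, rel=1e-9)

    def test_zero_events_undefined(self):
        chi2, p = logrank([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])
        assert chi2 is UNDEFINED and p is UNDEFINED


class TestCox:
    def test_null_binary_covariate_hr_near_one(self):
        rng = np.random.default_rng(5)
        n = 1000
        frame = pd.DataFrame(
            {
                "time": rng.exponential(10, n),
                "event": 1,
                "group": rng.integers(0, 2, n),
            }
        )
        (res,) = cox_fit(frame, ["group"])
        assert 0.8 <= res.hr <= 1.25
        assert res.ci_low <= res.hr <= res.ci_high

    def test_recovers_planted_hazard_ratio(self):
        surv = SurvivalConfig(hr_responder=0.4, censor_rate=0.0)
        cfg = SyntheticConfig(
            n_samples=400, n_nonresponders=200, n_features=5, seed=6, survival=surv
        )
        cohort = generate_cohort(cfg)
        frame = pd.DataFrame(
            {
                "time": cohort["os_time"],
                "event": cohort["os_event"],
                "responder": labels_from_cohort(cohort),
            }
        )
        (res,) = cox_fit(frame, ["responder"])
        assert abs(res.hr - 0.4) <= 0.1  # within 25% of the generating value
        assert res.p_value < 1e-6

    def test_duplicated_covariate_rank_deficiency_diagnostic(self):
        rng = np.random.default_rng(7)
        frame = pd.DataFrame(
            {
                "time": rng.exponential(10, 50),
                "event": 1,
                "x1": rng.normal(size=50),
            }
        )
        frame["x2"] = frame["x1"]
        with pytest.raises(ValueError, match="rank-deficient"):
            cox_fit(frame, ["x1", "x2"], model_type="multivariate")

    def test_logrank_p_close_to_cox_p_at_large_n(self):
        surv = SurvivalConfig(hr_responder=0.7, censor_rate=0.0)
        cfg = SyntheticConfig(
            n_samples=500, n_nonresponders=250, n_features=5, seed=8, survival=surv
        )
        cohort = generate_cohort(cfg)
        y = labels_from_cohort(cohort)
        _, p_lr = logrank(cohort["os_time"], cohort["os_event"], y)
        frame = pd.DataFrame(
            {"time": cohort["os_time"], "event": cohort["os_event"], "responder": y}
        )
        (res,) = cox_fit(frame, ["responder"])
        assert np.log10(p_lr) == pytest.approx(np.log10(res.p_value), abs=1.0)


class TestComparePredictedGroups:
    def _cohort_frames(self, seed=9, hr=0.4):
        surv = SurvivalConfig(hr_responder=hr, censor_rate=0.1)
        cfg = SyntheticConfig(n_features=5, seed=seed, survival=surv)
        cohort = generate_cohort(cfg)
        survival_records = cohort[
            ["patient_id", "os_time", "os_event", "pfs_time", "pfs_event"]
        ]
        labels = cohort[["patient_id", "response_label"]]
        return cohort, survival_records, labels

    def test_perfect_predictions_reproduce_actual_medians(self):
        cohort, records, labels = self._cohort_frames()
        preds = pd.DataFrame(
            {
                "patient_id": cohort["patient_id"],
                "predicted_class": (cohort["response_label"] == "responder").astype(int),
            }
        )
        comp = compare_predicted_groups(preds, records, labels)
        groups = comp.groups.set_index(["group", "endpoint"])["km_median"]
        for endpoint in ("OS", "PFS"):
            assert groups["predicted_responder", endpoint] == pytest.approx(
                groups["actual_responder", endpoint], nan_ok=True
            )
            assert groups["predicted_nonresponder", endpoint] == pytest.approx(
                groups["actual_nonresponder", endpoint], nan_ok=True
            )

    def test_accurate_classifier_preserves_survival_separation(self):
        cohort, records, labels = self._cohort_frames(seed=10)
        rng = np.random.default_rng(0)
        actual = (cohort["response_label"] == "responder").to_numpy().astype(int)
        noisy = actual.copy()
        flip = rng.random(len(noisy)) < 0.1  # a high-MCC imperfect classifier
        noisy[flip] = 1 - noisy[flip]
        preds = pd.DataFrame(
            {"patient_id": cohort["patient_id"], "predicted_class": noisy}
        )
        comp = compare_predicted_groups(preds, records, labels)
        groups = comp.groups.set_index(["group", "endpoint"])["km_median"]
        assert (
            groups["predicted_responder", "OS"] > groups["predicted_nonresponder", "OS"]
        )
        assert set(comp.comparisons["group_a"]) == {
            "actual_responder",
            "predicted_responder",
            "actual_nonresponder",
        }

    def test_unjoinable_patients_dropped_and_counted(self):
        cohort, records, labels = self._cohort_frames(seed=11)
        preds = pd.DataFrame(
            {
                "patient_id": list(cohort["patient_id"]) + ["GHOST-01"],
                "predicted_class": [0] * len(cohort) + [1],
            }
        )
        comp = compare_predicted_groups(preds, records, labels)
        assert comp.n_dropped == 1
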