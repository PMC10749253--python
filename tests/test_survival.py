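"""Thresholding, majority vote, KM, log-rank and the Cox predictor."""

import itertools

import numpy as np
import pandas as pd
import pytest

from truet import simulate, survival

from oracles import hand_logrank


class TestRocThreshold:
    def test_perfectly_separated_four_points(self):
        """Deaths at the two low densities -> cutoff in (200, 900], J = 1."""
        cut = survival.roc_threshold([100, 200, 900, 1000], [1, 1, 0, 0])
        assert 200 < cut <= 900
        assert cut == 900.0      # lowest candidate achieving J = 1

    def test_permuted_labels_agree_with_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        d = rng.gamma(4, 150, 200)
        y = rng.permutation(np.repeat([0, 1], 100))
        cut = survival.roc_threshold(d, y)
        best_j, best_c = -np.inf, None
        for c in np.unique(d):                     # independent scan
            call = d < c
            j = (call & (y == 1)).sum() / 100 + (~call & (y == 0)).sum() / 100 - 1
            if j > best_j:
                best_j, best_c = j, c
        assert cut == best_c
        call = d < cut
        j_chosen = (call & (y == 1)).sum() / 100 \
            + (~call & (y == 0)).sum() / 100 - 1
        assert abs(j_chosen) < 0.25                # near 0 under the null

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            survival.roc_threshold([1.0, 2.0], [1, 1])


class TestTruetStatus:
    THR = {"cd3": 500.0, "cd4": 300.0, "cd8": 700.0}

    def test_all_above_is_high(self):
        rec = {"cd3_density": 600, "cd4_density": 400, "cd8_density": 800}
        assert survival.truet_status(rec, self.THR) == "High"

    def test_all_below_is_low(self):
        rec = {"cd3_density": 400, "cd4_density": 200, "cd8_density": 600}
        assert survival.truet_status(rec, self.THR) == "Low"

    def test_truth_table_all_8_cases(self):
        """Low iff >= 2 markers strictly below their cutoffs."""
        for bits in itertools.product([0, 1], repeat=3):
            rec = {
                "cd3_density": 400 if bits[0] else 600,
                "cd4_density": 200 if bits[1] else 400,
                "cd8_density": 600 if bits[2] else 800,
            }
            expected = "Low" if sum(bits) >= 2 else "High"
            assert survival.truet_status(rec, self.THR) == expected

    def test_equality_at_cutoff_votes_high(self):
        rec = {"cd3_density": 500, "cd4_density": 300, "cd8_density": 800}
        assert survival.truet_status(rec, self.THR) == "High"

    def test_two_marker_mode_requires_both_below(self):
        rec = {"cd3_density": 400, "cd8_density": 800}
        assert survival.truet_status(rec, self.THR,
                                     markers=("cd3", "cd8")) == "High"
        rec["cd8_density"] = 600
        assert survival.truet_status(rec, self.THR,
                                     markers=("cd3", "cd8")) == "Low"

    def test_fewer_than_two_markers_undetermined(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            survival.truet_status({"cd3_density": 100}, self.THR)

    def test_missing_marker_votes_among_available(self):
        rec = {"cd3_density": 400, "cd4_density": 200,
               "cd8_density": float("nan")}
        assert survival.truet_status(rec, self.THR) == "Low"


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        times, surv = survival.km_curve([1, 2, 3], [0, 0, 0])
        assert np.all(surv == 1.0)

    def test_all_events_hand_product_limit(self):
        """times {1,2,3} all events -> S = 2/3, 1/3, 0."""
        times, surv = survival.km_curve([1, 2, 3], [1, 1, 1])
        lookup = dict(zip(times, surv))
        assert np.isclose(lookup[1.0], 2 / 3)
        assert np.isclose(lookup[2.0], 1 / 3)
        assert np.isclose(lookup[3.0], 0.0)

    def test_censoring_hand_product_limit(self):
        """4 subjects (1E, 2C, 3E, 3C): S(1)=3/4, S(3)=3/8."""
        times, surv = survival.km_curve([1, 2, 3, 3], [1, 0, 1, 0])
        lookup = dict(zip(times, surv))
        assert np.isclose(lookup[1.0], 3 / 4)
        assert np.isclose(lookup[3.0], 3 / 8)

    def test_starts_at_one_non_increasing(self):
        rng = np.random.default_rng(0)
        times, surv = survival.km_curve(rng.exponential(5, 50),
                                        rng.binomial(1, 0.7, 50))
        assert surv[0] == 1.0
        assert np.all(np.diff(surv) <= 1e-12)

    def test_fully_observed_equals_one_minus_ecdf(self):
        t = np.array([1.0, 2.0, 2.0, 4.0, 7.0])
        times, surv = survival.km_curve(t, np.ones_like(t))
        for ti, si in zip(times[1:], surv[1:]):
            assert np.isclose(si, 1 - np.mean(t <= ti))

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            survival.km_curve([-1.0, 2.0], [1, 1])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        g = (np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]))
        stat, p = survival.logrank_test(g, g)
        assert np.isclose(stat, 0.0, atol=1e-12)
        assert np.isclose(p, 1.0)

    def test_small_fixture_matches_hand_tally(self):
        t1, e1 = np.array([1.0, 3.0, 5.0]), np.array([1, 1, 0])
        t2, e2 = np.array([2.0, 4.0, 6.0]), np.array([1, 0, 1])
        stat, _ = survival.logrank_test((t1, e1), (t2, e2))
        assert np.isclose(stat, hand_logrank(t1, e1, t2, e2), atol=1e-9)

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(1)
        g1 = (rng.exponential(5, 30), rng.binomial(1, 0.8, 30))
        g2 = (rng.exponential(3, 30), rng.binomial(1, 0.8, 30))
        s12, p12 = survival.logrank_test(g1, g2)
        s21, p21 = survival.logrank_test(g2, g1)
        assert np.isclose(s12, s21) and np.isclose(p12, p21)

    def test_no_events_flagged_nan(self):
        g = (np.array([1.0, 2.0]), np.array([0, 0]))
        stat, p = survival.logrank_test(g, g)
        assert np.isnan(stat) and np.isnan(p)


class TestStratify:
    def _cohort(self, seed=0, n=300, hr=3.0):
        return simulate.simulate_cohort(simulate.CohortSimConfig(
            n_patients=n, hazard_ratio_cold_vs_hot=hr, seed=seed))

    def test_concordant_densities_separate_survival(self):
        result = survival.stratify(self._cohort(seed=5))
        assert set(result.group_sizes) == {"High", "Low"}
        assert result.logrank_p < 0.05

    def test_zero_thresholds_single_group_flagged(self):
        thr = survival.ThresholdSet(0.0, 0.0, 0.0)
        result = survival.stratify(self._cohort(seed=1), thr)
        assert result.group_sizes.get("High") == 300
        assert result.logrank_p is None
        assert any("skipped" in f for f in result.flags)

    def test_km_curves_valid_step_functions(self):
        result = survival.stratify(self._cohort(seed=2))
        for times, surv in result.km_curves.values():
            assert surv[0] == 1.0
            assert np.all((surv >= 0) & (surv <= 1))
            assert np.all(np.diff(surv) <= 1e-12)


class TestCox:
    def test_recovers_binary_covariate_hazard_ratio(self):
        rng = np.random.default_rng(0)
        n = 600
        x = rng.binomial(1, 0.5, n)
        t = rng.exponential(1.0 / (0.1 * np.exp(np.log(2.0) * x)))
        df = pd.DataFrame({"patient_id": [str(i) for i in range(n)],
                           "time": t, "event": 1})
        status = pd.Series(np.where(x == 1, "Low", "High"),
                           index=df["patient_id"])
        cph = survival.fit_cox(df, status=status, covariates=["truet_low"])
        hr = float(np.exp(cph.params_["truet_low"]))
        assert 1.6 < hr < 2.4

    def test_zero_covariate_baseline_equals_nelson_aalen(self):
        from lifelines import CoxPHFitter, NelsonAalenFitter
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 80)
        e = rng.binomial(1, 0.8, 80)
        df = pd.DataFrame({"time": t, "event": e})
        cph = CoxPHFitter().fit(df, "time", "event")
        naf = NelsonAalenFitter().fit(t, e)
        cum = cph.baseline_cumulative_hazard_.iloc[:, 0]
        na = naf.cumulative_hazard_.iloc[:, 0].reindex(cum.index).ffill()
        np.testing.assert_allclose(cum.values, na.values, atol=1e-8)

    def test_no_events_rejected(self):
        df = simulate.simulate_cohort(simulate.CohortSimConfig(
            n_patients=20, seed=0))
        df["event"] = 0
        with pytest.raises(ValueError, match="no events"):
            survival.fit_cox(df)


class TestPredictSurvival5yr:
    def _fit(self):
        cohort = simulate.simulate_cohort(simulate.CohortSimConfig(
            n_patients=300, seed=4))
        result = survival.stratify(cohort)
        return survival.fit_cox(cohort, status=result.status), cohort, result

    def test_baseline_identity_for_zero_covariates(self):
        """x = 0 returns the at-zero baseline survival S0(t) = exp(-H0(t))."""
        cph, cohort, _ = self._fit()
        x = {c: 0.0 for c in cph.params_.index}
        prob, (times, surv), _ = survival.predict_survival_5yr(cph, x)
        beta = cph.params_
        mean = pd.Series(cph._norm_mean).reindex(beta.index).astype(float)
        h0 = cph.baseline_cumulative_hazard_.iloc[:, 0].to_numpy() \
            * np.exp(-(beta @ mean))
        np.testing.assert_allclose(surv, np.exp(-h0), atol=1e-10)

    def test_matches_lifelines_prediction_for_random_covariates(self):
        cph, cohort, _ = self._fit()
        rng = np.random.default_rng(5)
        x = {c: float(v) for c, v in zip(
            cph.params_.index, rng.normal(0, 0.5, len(cph.params_)))}
        x["age"] = 70.0
        _, (times, surv), _ = survival.predict_survival_5yr(cph, x)
        sf = cph.predict_survival_function(pd.DataFrame([x]))
        np.testing.assert_allclose(surv, sf.iloc[:, 0].to_numpy(), atol=1e-8)

    def test_higher_risk_lowers_curve_pointwise(self):
        cph, cohort, _ = self._fit()
        low = {c: 0.0 for c in cph.params_.index}
        high = dict(low)
        high["truet_low"] = 1.0
        assert cph.params_["truet_low"] > 0
        _, (_, s_low), _ = survival.predict_survival_5yr(cph, low)
        _, (_, s_high), _ = survival.predict_survival_5yr(cph, high)
        assert np.all(s_high <= s_low + 1e-12)

    def test_closed_form_five_year_value(self):
        """S(5|x) = S0(5)^exp(beta'x) with S0 the at-zero baseline."""
        cph, _, _ = self._fit()
        x = {c: 0.0 for c in cph.params_.index}
        x["truet_low"] = 1.0
        prob, (times, surv), _ = survival.predict_survival_5yr(cph, x)
        x0 = {c: 0.0 for c in cph.params_.index}
        _, (_, s0), _ = survival.predict_survival_5yr(cph, x0)
        s0_5 = s0[times <= 5.0][-1]
        expected = s0_5 ** np.exp(float(cph.params_["truet_low"]))
        assert np.isclose(prob, expected, rtol=1e-9)

    def test_curves_bounded_and_monotone(self):
        cph, cohort, result = self._fit()
        x = {c: 0.0 for c in cph.params_.index}
        _, (times, surv), _ = survival.predict_survival_5yr(cph, x)
        assert np.all((surv >= 0) & (surv <= 1))
        assert np.all(np.diff(surv) <= 1e-12)

    def test_extrapolation_flagged(self):
        cph, _, _ = self._fit()
        x = {c: 0.0 for c in cph.params_.index}
        prob, _, extrapolated = survival.predict_survival_5yr(cph, x,
                                                              horizon=50.0)
        assert extrapolated


def test_derive_thresholds_recovers_separating_cutoffs():
    """Cold patients die faster and have low densities, so the ROC cutoffs
    should land between the cold and hot density clusters."""
    cohort = simulate.simulate_cohort(simulate.CohortSimConfig(
        n_patients=600, hazard_ratio_cold_vs_hot=6.0, seed=9))
    thr = survival.derive_thresholds(cohort)
    assert thr.derivation == "roc"
    hot = cohort["latent_hot"] == 1
    for m in ("cd3", "cd4", "cd8"):
        lo = cohort.loc[~hot, f"{m}_density"].median()
        hi = cohort.loc[hot, f"{m}_density"].median()
        assert lo < getattr(thr, m) < hi
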