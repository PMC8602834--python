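"""Survival estimators vs hand computations and independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import reactsig as rs
from reactsig.datatypes import ValidationError
from reactsig.derivation import auc_from_groups
from reactsig.survival import _cox_loglik_grad_hess, _rmst_single


class TestKMCurve:
    def test_hand_product_limit(self):
        km = rs.km_curve([1, 2, 3], [1, 1, 1])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert km.median == 2.0

    def test_all_censored(self):
        km = rs.km_curve([1, 2, 3], [0, 0, 0])
        assert km.survival.size == 0
        assert km.at(5.0) == 1.0
        assert km.median is None

    def test_single_event(self):
        km = rs.km_curve([5], [1])
        assert km.at(5.0) == 0.0
        assert km.median == 5.0

    def test_matches_lifelines(self, bulk_cohort):
        from lifelines import KaplanMeierFitter

        _, surv, _ = bulk_cohort
        km = rs.km_curve(surv["time"], surv["event"])
        kmf = KaplanMeierFitter().fit(surv["time"], surv["event"])
        for t in np.quantile(surv["time"], [0.2, 0.5, 0.8]):
            assert km.at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10
            )

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValidationError):
            rs.km_curve([0.0, 1.0], [1, 1])


def hand_logrank_two_groups(times, events, groups):
    """Literal O-E/V transcription of the two-group log-rank statistic."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(groups)
    labels = np.unique(g)
    o_minus_e = 0.0
    var = 0.0
    for ti in np.unique(t[e == 1]):
        at = t >= ti
        n = at.sum()
        d = ((t == ti) & (e == 1)).sum()
        n1 = (at & (g == labels[0])).sum()
        d1 = ((t == ti) & (e == 1) & (g == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 1, 1, 1, 1]
        g = ["a", "a", "a", "b", "b", "b"]
        res = rs.logrank_test(t, e, g)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_hand_computed_separated_groups(self):
        t = [1, 2, 3, 4]
        e = [1, 1, 1, 1]
        g = ["a", "a", "b", "b"]
        res = rs.logrank_test(t, e, g)
        assert res["statistic"] == pytest.approx(hand_logrank_two_groups(t, e, g))

    def test_label_permutation_symmetry(self, rng):
        t = rng.exponential(5, size=30)
        e = rng.integers(0, 2, size=30)
        e[0] = 1
        g = rng.integers(0, 2, size=30)
        a = rs.logrank_test(t, e, g)
        b = rs.logrank_test(t, e, 1 - g)
        assert a["statistic"] == pytest.approx(b["statistic"])

    def test_matches_lifelines_multigroup(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        t = rng.exponential(5, size=60)
        e = rng.integers(0, 2, size=60)
        e[:3] = 1
        g = rng.integers(0, 3, size=60)
        res = rs.logrank_test(t, e, g)
        ll = multivariate_logrank_test(t, g, e)
        assert res["statistic"] == pytest.approx(ll.test_statistic, rel=1e-9)
        assert res["p"] == pytest.approx(ll.p_value, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            rs.logrank_test([1, 2], [1, 1], ["a", "a"])


class TestCoxFit:
    def test_grid_search_oracle_six_subjects(self):
        """Newton beta-hat matches a 1e-4 grid search of the partial likelihood."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([[1.0], [0.0], [1.0], [0.0], [0.0], [1.0]])
        xc = x - x.mean()
        grid = np.arange(-3.0, 3.0, 1e-4)
        lls = [
            _cox_loglik_grad_hess(np.array([b]), xc, t, e, "efron")[0] for b in grid
        ]
        beta_grid = grid[int(np.argmax(lls))]
        fit = rs.cox_fit(x, t, e)
        assert fit.beta[0] == pytest.approx(beta_grid, abs=1e-3)

    def test_covariate_rescaling_invariance(self, bulk_cohort):
        _, surv, u = bulk_cohort
        f1 = rs.cox_fit(u, surv["time"], surv["event"])
        f2 = rs.cox_fit(10.0 * u, surv["time"], surv["event"])
        assert f2.beta[0] == pytest.approx(f1.beta[0] / 10.0, rel=1e-6)
        assert f2.loglik == pytest.approx(f1.loglik, rel=1e-9)

    def test_matches_lifelines_efron(self, bulk_cohort):
        from lifelines import CoxPHFitter

        _, surv, u = bulk_cohort
        df = pd.DataFrame({"u": u.reindex(surv.index), "time": surv["time"], "event": surv["event"]})
        cph = CoxPHFitter().fit(df, "time", "event")
        fit = rs.cox_fit(df[["u"]], surv["time"], surv["event"])
        assert fit.beta[0] == pytest.approx(cph.params_["u"], abs=1e-6)
        assert fit.se[0] == pytest.approx(cph.standard_errors_["u"], abs=1e-6)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, rel=1e-9)

    def test_aic_and_hr_identities(self, bulk_cohort):
        _, surv, u = bulk_cohort
        fit = rs.cox_fit(u, surv["time"], surv["event"])
        assert fit.aic == -2.0 * fit.loglik + 2.0
        assert fit.hr[0] == np.exp(fit.beta[0])
        lo, hi = fit.ci[0]
        assert lo < fit.hr[0] < hi

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError, match="information"):
            rs.cox_fit(np.ones(5), [1, 2, 3, 4, 5], [1, 1, 1, 1, 1])

    def test_perfect_separation_flagged(self):
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        e = np.ones(6, dtype=int)
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        fit = rs.cox_fit(x, t, e)
        assert any("monotone" in f for f in fit.flags)


def brute_force_cindex(risk, times, events):
    """Independent O(n^2) pair loop with explicit usability rules."""
    conc = ties = usable = 0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shorter = (events[i] and times[i] < times[j]) or (
                events[i] and not events[j] and times[i] == times[j]
            )
            if not shorter:
                continue
            usable += 1
            if risk[i] > risk[j]:
                conc += 1
            elif risk[i] == risk[j]:
                ties += 1
    return (conc + 0.5 * ties) / usable


class TestConcordance:
    def test_perfect_and_reversed(self):
        assert rs.concordance_index([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0
        assert rs.concordance_index([1, 2, 3], [1, 2, 3], [1, 1, 1]) == 0.0

    def test_brute_force_oracle_random_instance(self, rng):
        n = 20
        risk = rng.normal(size=n).round(1)  # rounding forces risk ties
        times = rng.integers(1, 8, size=n).astype(float)  # and time ties
        events = rng.integers(0, 2, size=n)
        events[0] = 1
        got = rs.concordance_index(risk, times, events)
        assert got == pytest.approx(brute_force_cindex(risk, times, events))

    def test_risk_monotone_transform_invariance(self, rng):
        n = 30
        risk = rng.normal(size=n)
        times = rng.exponential(5, size=n)
        events = rng.integers(0, 2, size=n)
        events[:2] = 1
        a = rs.concordance_index(risk, times, events)
        b = rs.concordance_index(np.exp(risk), times, events)
        assert a == pytest.approx(b)

    def test_cox_predictor_beats_chance_on_cohort(self, bulk_cohort):
        _, surv, u = bulk_cohort
        risk = -u.reindex(surv.index)  # protective latent effect
        c = rs.concordance_index(risk, surv["time"], surv["event"])
        assert c > 0.55

    def test_no_usable_pairs(self):
        with pytest.raises(ValidationError):
            rs.concordance_index([1, 2], [5, 5], [1, 1])


def naive_km_weighted_tdauc(risk, times, events, t_star):
    """Literal transcription of the KM-weighted sensitivity/specificity AUC."""
    risk = np.asarray(risk, float)
    s_all = rs.km_curve(times, events).at(t_star)
    sens, fpr = [1.0], [1.0]
    for c in np.unique(risk):
        above = risk > c
        p = above.mean()
        s_c = rs.km_curve(np.asarray(times)[above], np.asarray(events)[above]).at(t_star) if p > 0 else 0.0
        se = (1 - s_c) * p / (1 - s_all)
        sp = (s_all - s_c * p) / s_all
        sens.append(min(max(se, 0.0), 1.0))
        fpr.append(min(max(1 - sp, 0.0), 1.0))
    pts = sorted(zip(fpr, sens))
    xs = [q[0] for q in pts]
    ys = [q[1] for q in pts]
    return np.trapezoid(ys, xs)


class TestTimeDependentAUC:
    def test_censor_free_reduces_to_binary_auc(self, rng):
        n = 80
        risk = rng.normal(size=n)
        times = rng.exponential(np.exp(-risk), size=n)
        events = np.ones(n, dtype=int)
        t_star = float(np.median(times))
        cases = risk[times <= t_star]
        controls = risk[times > t_star]
        plain = auc_from_groups(cases[None, :], controls[None, :])[0]
        got = rs.time_dependent_auc(risk, times, events, t_star)
        assert got == pytest.approx(plain, abs=1e-10)

    def test_null_risk_near_half(self, rng):
        n = 2000
        times = rng.exponential(5, size=n)
        events = (rng.random(n) < 0.8).astype(int)
        risk = rng.normal(size=n)  # independent of survival
        got = rs.time_dependent_auc(risk, times, events, float(np.median(times)))
        assert abs(got - 0.5) < 0.03

    def test_transcription_oracle_with_censoring(self):
        risk = np.array([0.3, 1.2, -0.5, 0.8, 0.1, 2.0, -1.0, 0.6])
        times = np.array([2.0, 1.0, 5.0, 3.0, 4.0, 0.5, 6.0, 2.5])
        events = np.array([1, 1, 1, 0, 1, 1, 1, 1])  # one censored subject
        t_star = 3.5
        got = rs.time_dependent_auc(risk, times, events, t_star)
        want = naive_km_weighted_tdauc(risk, times, events, t_star)
        assert got == pytest.approx(want, abs=1e-10)

    def test_no_cases_rejected(self):
        with pytest.raises(ValidationError):
            rs.time_dependent_auc([1, 2], [5.0, 6.0], [1, 1], 1.0)


class TestRMST:
    def test_no_events_rmst_equals_tau(self):
        res = rs.rmst_ratio(
            [5, 6, 7, 5, 6, 7], [0, 0, 0, 0, 0, 0], ["a"] * 3 + ["b"] * 3, tau=4.0
        )
        assert res["rmst"]["a"] == pytest.approx(4.0)
        assert res["rmst"]["b"] == pytest.approx(4.0)
        assert res["ratio"] == pytest.approx(1.0)

    def test_unit_step_rectangle(self):
        """All subjects fail at t=1: survival is a unit step, area 1 on [0,2]."""
        rm, _ = _rmst_single([1.0, 1.0, 1.0], [1, 1, 1], tau=2.0)
        assert rm == pytest.approx(1.0)

    def test_hand_step_integration_two_arms(self):
        # arm a: events at 1,2 among 5 subjects; KM = .8 on [1,2), .6 on [2,4]
        ta = [1, 2, 4, 4, 4]
        ea = [1, 1, 0, 0, 0]
        # arm b: event at 3; KM = 1 on [0,3), .2? no: 1 event among 5 at t=3
        tb = [3, 4, 4, 4, 4]
        eb = [1, 0, 0, 0, 0]
        res = rs.rmst_ratio(ta + tb, ea + eb, ["a"] * 5 + ["b"] * 5, tau=4.0)
        want_a = 1.0 * 1 + 0.8 * 1 + 0.6 * 2
        want_b = 1.0 * 3 + 0.8 * 1
        assert res["rmst"]["a"] == pytest.approx(want_a)
        assert res["rmst"]["b"] == pytest.approx(want_b)
        assert res["ratio"] == pytest.approx(want_b / want_a)

    def test_matches_lifelines_rmst(self, bulk_cohort):
        from lifelines import KaplanMeierFitter
        from lifelines.utils import restricted_mean_survival_time

        _, surv, _ = bulk_cohort
        tau = float(np.quantile(surv["time"], 0.7))
        rm, _ = _rmst_single(surv["time"].to_numpy(), surv["event"].to_numpy(), tau)
        kmf = KaplanMeierFitter().fit(surv["time"], surv["event"])
        want = restricted_mean_survival_time(kmf, t=tau)
        assert rm == pytest.approx(float(want), abs=1e-8)

    def test_tau_beyond_follow_up_rejected(self):
        # arm a ends censored at t=2 with survival still positive, so the
        # curve is undetermined beyond its follow-up
        with pytest.raises(ValidationError, match="reduce tau"):
            rs.rmst_ratio([1, 2, 1, 2], [1, 0, 1, 1], ["a", "a", "b", "b"], tau=10.0)


class TestStratifyAndRisk:
    def test_even_split(self):
        labels = rs.stratify_median(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert list(labels) == ["low", "low", "high", "high"]

    def test_odd_median_goes_low(self):
        labels = rs.stratify_median(pd.Series([1.0, 2.0, 3.0]))
        assert list(labels) == ["low", "low", "high"]

    def test_duplicated_median_all_low(self):
        labels = rs.stratify_median(pd.Series([1.0, 2.0, 2.0, 2.0, 5.0]))
        assert list(labels) == ["low", "low", "low", "low", "high"]

    def test_constant_scores_rejected(self):
        with pytest.raises(ValidationError):
            rs.stratify_median(pd.Series([1.0, 1.0, 1.0]))

    def test_linear_risk_single_gene(self, tiny_expr):
        risk = rs.linear_risk_score(tiny_expr, {"g0": 1.0})
        assert np.allclose(risk, tiny_expr.values.loc["g0"])

    def test_linear_risk_arithmetic(self):
        expr = rs.ExpressionMatrix(
            pd.DataFrame({"s": [3.0, 4.0]}, index=["a", "b"]), "log2"
        )
        risk = rs.linear_risk_score(expr, {"a": 2.0, "b": -1.0})
        assert risk["s"] == pytest.approx(2.0)

    def test_negate_flag_for_score_signatures(self, bulk_cohort, small_signature):
        expr, _, _ = bulk_cohort
        sv = rs.score_samples(expr, small_signature, rs.ScoringConfig(method="mean"))
        risk = rs.score_to_risk(sv)
        assert np.allclose(risk, -sv.scores)

    def test_missing_genes_strict_mode(self, tiny_expr):
        with pytest.raises(ValidationError, match="strict"):
            rs.linear_risk_score(tiny_expr, {"g0": 1.0, "absent": 2.0}, strict=True)
        risk = rs.linear_risk_score(tiny_expr, {"g0": 1.0, "absent": 2.0})
        assert risk.attrs["missing_genes"] == ["absent"]


class TestPowerAndCalibration:
    def test_median_split_logrank_power(self, small_signature):
        """Log-rank on true-score median split is strongly powered at n=500."""
        hits = 0
        for seed in range(20):
            design = rs.CohortDesign(n_samples=500, n_genes=20, latent_effect=-0.7, seed=seed)
            _, surv, u = rs.gen_bulk_cohort(design, small_signature)
            grp = rs.stratify_median(u.reindex(surv.index))
            res = rs.logrank_test(surv["time"], surv["event"], grp)
            hits += res["p"] < 0.01
        assert hits >= 18  # >= 90% of seeds

    def test_logrank_type_one_error(self, rng):
        """Null log-rank rejects at ~nominal rate over 100 seeds."""
        rejections = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            t = r.exponential(5, size=60)
            e = (r.random(60) < 0.8).astype(int)
            g = r.integers(0, 2, size=60)
            if e.sum() == 0 or len(np.unique(g)) < 2:
                continue
            rejections += rs.logrank_test(t, e, g)["p"] < 0.05
        assert rejections <= 10

    def test_compare_cindex_detects_informative_risk(self, bulk_cohort):
        _, surv, u = bulk_cohort
        rng = np.random.default_rng(1)
        noise = rng.normal(size=len(surv))
        res = rs.compare_cindex(
            -u.reindex(surv.index).to_numpy(), noise, surv["time"], surv["event"],
            n_boot=200, seed=2,
        )
        assert res["delta_c"] > 0
        assert res["ci_low"] > 0
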