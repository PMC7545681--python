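"""Oracle and property tests for the self-implemented survival statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from morphome import (
    FitError,
    cox_fit,
    cox_loglik,
    cox_score,
    cox_score_test,
    fisher_exact,
    kaplan_meier,
    logrank_test,
)


def breslow_loglik_reference(beta, x, time, event):
    """Explicitly coded one-covariate Breslow partial likelihood."""
    ll = 0.0
    for u in sorted(set(time[event])):
        at_risk = time >= u
        d = int(((time == u) & event).sum())
        ll += float(beta * x[(time == u) & event].sum())
        ll -= d * math.log(np.exp(beta * x[at_risk]).sum())
    return ll


def golden_section_max(f, lo, hi, tol=1e-9):
    gr = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - gr * (b - a), a + gr * (b - a)
    while abs(b - a) > tol:
        if f(c) > f(d):
            b, d = d, c
            c = b - gr * (b - a)
        else:
            a, c = c, d
            d = a + gr * (b - a)
    return (a + b) / 2


class TestCoxFit:
    def test_symmetric_relabeling_gives_zero(self):
        # exchanging the two groups' event-time patterns forces beta = 0
        time = np.array([1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0])
        event = np.ones(8, bool)
        x = np.array([0, 0, 1, 1, 1, 1, 0, 0], float)
        fit = cox_fit(x, time, event)
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-8)

    def test_matches_grid_plus_golden_section_oracle(self, surv_simple):
        x, time, event = surv_simple
        fit = cox_fit(x, time, event)
        f = lambda b: breslow_loglik_reference(b, x, time, event)
        grid = np.linspace(-5, 5, 2001)
        b0 = grid[np.argmax([f(b) for b in grid])]
        b_star = golden_section_max(f, b0 - 0.01, b0 + 0.01, tol=1e-10)
        assert fit.coefficients[0] == pytest.approx(b_star, abs=1e-6)
        assert fit.log_partial_likelihood == pytest.approx(f(b_star), abs=1e-9)

    def test_score_vanishes_at_optimum(self, surv_simple):
        x, time, event = surv_simple
        fit = cox_fit(x, time, event)
        assert abs(cox_score(fit.coefficients, x[:, None], time, event)[0]) < 1e-6

    def test_efron_ties_against_lifelines(self):
        from lifelines import CoxPHFitter
        import pandas as pd

        rng = np.random.default_rng(8)
        n = 80
        X = rng.normal(size=(n, 2))
        t = np.ceil(rng.exponential(10 / np.exp(X @ [0.6, -0.4])))  # heavy ties
        e = rng.random(n) < 0.7
        fit = cox_fit(X, t, e, ties="efron")
        df = pd.DataFrame(X, columns=["a", "b"]).assign(T=t, E=e)
        cph = CoxPHFitter().fit(df, "T", "E")  # lifelines default is Efron
        np.testing.assert_allclose(fit.coefficients, cph.params_.values, atol=2e-4)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.values, atol=2e-4)

    def test_hazard_ratio_ci_contains_hr(self, surv_simple):
        x, time, event = surv_simple
        fit = cox_fit(x, time, event)
        lo, hi = fit.ci95[0]
        assert lo < fit.hazard_ratios[0] < hi

    def test_separation_flags_nonconvergence(self):
        time = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        event = np.ones(6, bool)
        x = np.array([1, 1, 1, 0, 0, 0], float)  # perfect separation
        with pytest.warns(RuntimeWarning, match="monotone"):
            fit = cox_fit(x, time, event)
        assert not fit.converged

    def test_too_few_events_rejected(self):
        with pytest.raises(FitError):
            cox_fit(np.array([1.0, 0.0]), np.array([1.0, 2.0]), np.array([True, False]))

    def test_wald_ci_coverage(self):
        # 95% Wald interval should cover the true log-hazard in ~95% of
        # simulated cohorts (exponential baseline, known beta)
        rng = np.random.default_rng(77)
        beta_true = 0.7
        covered = 0
        n_rep = 500
        for _ in range(n_rep):
            x = rng.normal(size=150)
            t = rng.exponential(1.0 / (0.1 * np.exp(beta_true * x)))
            c = rng.uniform(0, 20, 150)
            time = np.minimum(t, c) + 1e-9
            event = t <= c
            fit = cox_fit(x, time, event)
            lo, hi = np.log(fit.ci95[0])
            covered += lo <= beta_true <= hi
        assert 0.93 <= covered / n_rep <= 0.97


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [False, False, False])
        assert km.event_times.size == 0
        assert math.isnan(km.median_survival)
        assert km.survival_at(2.5) == 1.0

    def test_hand_computed_product_limit(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [True, False, True])
        np.testing.assert_allclose(km.event_times, [1.0, 3.0])
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])
        assert km.median_survival == 3.0

    def test_all_events_at_one_time(self):
        km = kaplan_meier([5.0, 5.0, 5.0], [True, True, True])
        np.testing.assert_allclose(km.survival, [0.0])
        assert km.median_survival == 5.0

    def test_censored_at_event_time_still_at_risk(self):
        km = kaplan_meier([1.0, 1.0, 2.0], [True, False, True])
        # at t=1: 3 at risk, 1 event -> S=2/3; censoring removed after
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])

    @given(
        st.lists(st.floats(0.5, 50.0), min_size=1, max_size=30).map(sorted)
    )
    @settings(max_examples=60, deadline=None)
    def test_no_censoring_equals_one_minus_ecdf(self, times):
        times = np.asarray(times)
        km = kaplan_meier(times, np.ones(len(times), bool))
        for u in km.event_times:
            assert km.survival_at(u) == pytest.approx((times > u).mean(), abs=1e-12)

    def test_against_lifelines(self, medium_cohort):
        from lifelines import KaplanMeierFitter

        t = medium_cohort.clinical["time_months"].to_numpy()
        e = medium_cohort.clinical["event"].to_numpy(bool)
        km = kaplan_meier(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        theirs = kmf.survival_function_at_times(km.event_times).to_numpy()
        np.testing.assert_allclose(km.survival, theirs, atol=1e-12)
        assert km.median_survival == pytest.approx(kmf.median_survival_time_)


class TestLogrank:
    def test_identical_groups(self):
        t = [1.0, 2.0, 3.0]
        e = [True, True, False]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_fixed_fixture_matches_hand_sum(self):
        # frozen from the hand-summed O-E / hypergeometric-variance terms
        # (independently confirmed by lifelines.statistics.logrank_test)
        t1 = [3.0, 5.0, 7.0, 9.0, 11.0, 13.0]; e1 = [1, 0, 1, 1, 0, 1]
        t2 = [2.0, 4.0, 6.0, 8.0, 10.0, 12.0]; e2 = [1, 1, 0, 1, 1, 1]
        chi2, p = logrank_test(t1, e1, t2, e2)
        assert chi2 == pytest.approx(0.746812960979771, abs=1e-12)
        assert p == pytest.approx(0.3874871458845912, abs=1e-12)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(4)
        t1 = rng.exponential(5, 20) + 0.1
        t2 = t1 + 50.0
        e = np.ones(20, bool)
        chi2, p = logrank_test(t1, e, t2, e)
        assert p < 0.01

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(6)
        t1, t2 = rng.exponential(5, 15) + 0.1, rng.exponential(9, 12) + 0.1
        e1, e2 = rng.random(15) < 0.8, rng.random(12) < 0.8
        c12 = logrank_test(t1, e1, t2, e2)
        c21 = logrank_test(t2, e2, t1, e1)
        assert c12 == pytest.approx(c21)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1.0], [True])

    def test_score_test_equals_logrank_without_ties(self):
        rng = np.random.default_rng(11)
        n = 40
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(10, n) + rng.uniform(0, 1e-3, n)  # no ties
        e = rng.random(n) < 0.8
        chi2_lr, _ = logrank_test(t[x == 0], e[x == 0], t[x == 1], e[x == 1])
        chi2_score, _ = cox_score_test(x, t, e)
        assert chi2_score == pytest.approx(chi2_lr, abs=1e-6)


class TestFisherExact:
    def test_balanced_table(self):
        assert fisher_exact([[5, 5], [5, 5]]) == 1.0

    def test_degenerate_margin(self):
        assert fisher_exact([[0, 0], [3, 4]]) == 1.0

    @pytest.mark.parametrize(
        "table", [[[1, 9], [11, 3]], [[2, 7], [8, 2]], [[10, 2], [3, 15]], [[0, 5], [5, 0]]]
    )
    def test_matches_exact_enumeration(self, table):
        # independent oracle: exact rational hypergeometric enumeration
        (a, b), (c, d) = table
        r1, r2, c1 = a + b, c + d, a + c
        n = r1 + r2
        denom = math.comb(n, c1)
        support = range(max(0, c1 - r2), min(r1, c1) + 1)
        pmf = {k: math.comb(r1, k) * math.comb(r2, c1 - k) / denom for k in support}
        expected = sum(v for v in pmf.values() if v <= pmf[a] * (1 + 1e-7))
        assert fisher_exact(table) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("table", [[[1, 9], [11, 3]], [[4, 1], [20, 9]]])
    def test_matches_scipy(self, table):
        assert fisher_exact(table) == pytest.approx(
            stats.fisher_exact(table)[1], rel=1e-9
        )

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [2, 3]])


class TestCoxLoglik:
    def test_loglik_consistent_with_fit(self, surv_simple):
        x, time, event = surv_simple
        fit = cox_fit(x, time, event)
        assert cox_loglik(fit.coefficients, x[:, None], time, event) == pytest.approx(
            fit.log_partial_likelihood
        )
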