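import math

import numpy as np
import pandas as pd
import pytest

from predictc.errors import ValidationError
from predictc.survival import (
    cox_fit,
    cox_score_test,
    km_estimate,
    logrank_test,
    marker_survival_report,
    restricted_mean,
    survival_report,
)

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def brute_logrank_chi2(ta, ea, tb, eb):
    """Hand-enumerated hypergeometric O-E and V summation."""
    t = np.concatenate([ta, tb]).astype(float)
    e = np.concatenate([ea, eb]).astype(bool)
    g = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
    obs = exp = var = 0.0
    for ti in sorted(set(t[e])):
        at_risk = t >= ti
        n = at_risk.sum()
        n_a = (at_risk & (g == 0)).sum()
        dead = e & (t == ti)
        d = dead.sum()
        d_a = (dead & (g == 0)).sum()
        obs += d_a
        exp += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return (obs - exp) ** 2 / var


def brute_cox_beta(times, events, x, grid=None):
    """Grid-search maximization of the written-out Breslow partial likelihood."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    x = np.asarray(x, float)
    if grid is None:
        grid = np.linspace(-10, 10, 200001)  # 1e-4 spacing
    ll = np.zeros_like(grid)
    for ti in np.unique(times[events]):
        risk = times >= ti
        dead = (times == ti) & events
        ll += float(x[dead].sum()) * grid
        ll -= dead.sum() * np.log(np.exp(np.outer(grid, x[risk])).sum(axis=1))
    return float(grid[np.argmax(ll)])


# ---------------------------------------------------------------------------
# Kaplan-Meier and restricted mean
# ---------------------------------------------------------------------------


class TestKMEstimate:
    def test_no_censoring_mean_of_event_times(self):
        curve = km_estimate([2, 4], [True, True])
        assert np.allclose(curve.survival, [0.5, 0.0])
        assert curve.restricted_mean == pytest.approx(3.0)

    def test_single_event(self):
        assert km_estimate([5], [True]).restricted_mean == pytest.approx(5.0)

    def test_censored_product_limit_area(self):
        # events at 1 and 3, censored at 2: S = 1 on [0,1), 2/3 on [1,3)
        curve = km_estimate([1, 2, 3], [True, False, True], tau=3)
        assert curve.survival_at(0.5) == 1.0
        assert curve.survival_at(1.5) == pytest.approx(2 / 3)
        assert curve.restricted_mean == pytest.approx(7 / 3)
        assert curve.rm_ci[0] < 7 / 3 < curve.rm_ci[1]

    def test_restricted_mean_at_new_tau(self):
        curve = km_estimate([2, 4], [True, True])
        mean, ci = restricted_mean(curve, 4.0)
        assert mean == pytest.approx(3.0)
        mean2, _ = restricted_mean(curve, 2.0)
        assert mean2 == pytest.approx(2.0)  # S = 1 up to the first event

    def test_flat_curve_mean_equals_tau(self):
        with pytest.warns(UserWarning, match="censored"):
            curve = km_estimate([3, 5, 7], [False, False, False])
        assert curve.all_censored
        assert curve.restricted_mean == pytest.approx(curve.tau)

    def test_tau_beyond_follow_up_errors(self):
        curve = km_estimate([2, 4], [True, True])
        with pytest.raises(ValidationError, match="exceeds"):
            restricted_mean(curve, 10.0)

    def test_survival_non_increasing(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(10, size=60)
        e = rng.random(60) < 0.7
        curve = km_estimate(t, e)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert curve.restricted_mean <= curve.tau + 1e-12

    def test_rmst_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        from lifelines.utils import restricted_mean_survival_time

        rng = np.random.default_rng(3)
        t = rng.exponential(12, size=80)
        e = rng.random(80) < 0.75
        tau = float(np.percentile(t, 90))
        curve = km_estimate(t, e, tau=tau)
        kmf = KaplanMeierFitter().fit(t, e)
        assert curve.restricted_mean == pytest.approx(
            float(restricted_mean_survival_time(kmf, t=tau)), rel=1e-9
        )


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------


class TestLogrank:
    def test_identical_groups_null(self):
        r = logrank_test([1, 2, 3], [1, 1, 1], [1, 2, 3], [1, 1, 1])
        assert r.chi2 == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_hand_enumerated_hypergeometric_sums(self):
        ta, ea, tb, eb = [1, 2], [1, 1], [3, 4], [1, 1]
        r = logrank_test(ta, ea, tb, eb)
        assert r.chi2 == pytest.approx(49 / 17, abs=1e-10)
        assert r.chi2 == pytest.approx(brute_logrank_chi2(ta, ea, tb, eb), abs=1e-10)

    def test_oracle_agreement_with_censoring(self):
        rng = np.random.default_rng(21)
        ta, tb = rng.exponential(5, 25), rng.exponential(9, 25)
        ea, eb = rng.random(25) < 0.8, rng.random(25) < 0.8
        r = logrank_test(ta, ea, tb, eb)
        assert r.chi2 == pytest.approx(brute_logrank_chi2(ta, ea, tb, eb), abs=1e-8)

    def test_label_swap_invariance(self):
        a = logrank_test([1, 5], [1, 0], [2, 3, 9], [1, 1, 0])
        b = logrank_test([2, 3, 9], [1, 1, 0], [1, 5], [1, 0])
        assert a.chi2 == pytest.approx(b.chi2)

    def test_zero_events_undefined(self):
        with pytest.raises(ValidationError, match="zero events"):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])

    def test_equals_cox_score_test_on_untied_data(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(6, size=40)
        e = rng.random(40) < 0.8
        g = np.repeat([0.0, 1.0], 20)
        e[t.argmin()] = True  # ensure at least one event
        chi2_lr = logrank_test(t[g == 0], e[g == 0], t[g == 1], e[g == 1]).chi2
        chi2_score, _ = cox_score_test(t, e, g)
        assert chi2_lr == pytest.approx(chi2_score, abs=1e-6)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


class TestCoxFit:
    def test_identical_event_patterns_give_null_effect(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 1, 1, 1, 1]
        x = [1, 1, 1, 0, 0, 0]
        fit = cox_fit(t, e, np.asarray(x, float))
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.hazard_ratios[0] == pytest.approx(1.0, abs=1e-8)

    def test_interior_mle_matches_closed_form_and_grid_search(self):
        # group-1 events interleaved with group-0 events; stationarity of the
        # partial likelihood gives exp(beta) = (1 + sqrt(17)) / 2
        t, e, x = [1, 2, 3, 4], [1, 1, 1, 1], [1.0, 0.0, 1.0, 0.0]
        fit = cox_fit(t, e, np.asarray(x))
        closed_form = math.log((1 + math.sqrt(17)) / 2)
        assert fit.converged
        assert fit.coef[0] == pytest.approx(closed_form, abs=1e-8)
        assert fit.coef[0] == pytest.approx(brute_cox_beta(t, e, x), abs=1e-4)

    def test_six_subject_instance_matches_grid_search(self):
        t = [1, 2, 3, 4, 5, 6]
        e = [1, 1, 0, 1, 1, 1]
        x = [1.0, 0.0, 1.0, 1.0, 0.0, 0.0]
        fit = cox_fit(t, e, np.asarray(x))
        assert fit.coef[0] == pytest.approx(brute_cox_beta(t, e, x), abs=1e-4)

    def test_monotone_likelihood_flagged_not_estimated(self):
        # the sole group-1 subject has the earliest event: the 2-term partial
        # likelihood x/(x+2) increases without bound in x = exp(beta)
        with pytest.warns(UserWarning, match="monotone"):
            fit = cox_fit([1, 2, 3], [1, 1, 1], np.asarray([1.0, 0.0, 0.0]))
        assert fit.monotone_likelihood
        assert not fit.converged

    def test_hr_invariant_under_time_scaling(self):
        rng = np.random.default_rng(17)
        t = rng.exponential(8, 30)
        e = rng.random(30) < 0.8
        x = rng.integers(0, 2, 30).astype(float)
        f1 = cox_fit(t, e, x)
        f2 = cox_fit(t * 7.3, e, x)
        assert f1.coef[0] == pytest.approx(f2.coef[0], abs=1e-7)

    def test_ci_brackets_hr_and_wald_p(self):
        rng = np.random.default_rng(2)
        t = np.concatenate([rng.exponential(4, 40), rng.exponential(12, 40)])
        e = rng.random(80) < 0.8
        x = np.repeat([1.0, 0.0], 40)
        fit = cox_fit(t, e, x)
        lo, hi = fit.ci[0]
        assert lo < fit.hazard_ratios[0] < hi
        assert 0 <= fit.wald_p[0] <= 1
        assert fit.model_chi2 > 0

    def test_efron_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        t = [1, 1, 2, 2, 3, 4, 5, 6]
        e = [1, 1, 1, 0, 1, 1, 0, 1]
        x = [1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0, 0.0]
        fit = cox_fit(t, e, np.asarray(x), ties="efron")
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        cph = CoxPHFitter().fit(df, "t", "e")
        assert fit.coef[0] == pytest.approx(float(cph.params_.iloc[0]), abs=1e-5)
        assert fit.se[0] == pytest.approx(float(cph.standard_errors_.iloc[0]), abs=1e-5)

    def test_breslow_and_efron_agree_without_ties(self):
        rng = np.random.default_rng(23)
        t = rng.exponential(5, 30)  # continuous: no ties
        e = rng.random(30) < 0.7
        x = rng.integers(0, 2, 30).astype(float)
        fb = cox_fit(t, e, x, ties="breslow")
        fe = cox_fit(t, e, x, ties="efron")
        assert fb.coef[0] == pytest.approx(fe.coef[0], abs=1e-9)

    def test_multivariate_fit_matches_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(31)
        n = 60
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.7 * x1 - 0.3 * x2) * 10)
        e = rng.random(n) < 0.8
        fit = cox_fit(t, e, pd.DataFrame({"x1": x1, "x2": x2}), ties="efron")
        df = pd.DataFrame({"t": t, "e": e, "x1": x1, "x2": x2})
        cph = CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(fit.coef, cph.params_.to_numpy(), atol=1e-5)


# ---------------------------------------------------------------------------
# Stratified reports
# ---------------------------------------------------------------------------


def _labels_clinical():
    rng = np.random.default_rng(4)
    n = 40
    labels = pd.DataFrame(
        {"patient_id": [f"P{i}" for i in range(n)],
         "label": ["responder"] * 25 + ["non_responder"] * 15}
    )
    clinical = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "pfs_months": rng.exponential(10, n) + 0.1,
            "pfs_event": rng.random(n) < 0.8,
            "os_months": rng.exponential(18, n) + 0.1,
            "os_event": rng.random(n) < 0.6,
        }
    )
    return labels, clinical


class TestSurvivalReport:
    def test_two_strata_table_and_p(self):
        labels, clinical = _labels_clinical()
        table, p = survival_report(labels, clinical, endpoint="pfs")
        assert set(table["label"]) == {"responder", "non_responder"}
        assert (table["mean_months"] <= table["tau"] + 1e-9).all()
        assert (table["ci_low"] <= table["mean_months"]).all()
        assert 0 <= p <= 1

    def test_single_group_p_absent(self):
        labels, clinical = _labels_clinical()
        solo = labels[labels["label"] == "responder"]
        table, p = survival_report(solo, clinical)
        assert len(table) == 1
        assert math.isnan(p)

    def test_empty_stratum_omitted_with_warning(self):
        labels, clinical = _labels_clinical()
        with pytest.warns(UserWarning, match="omitted"):
            table, _ = survival_report(
                labels, clinical, include_groups=["responder", "ghost"]
            )
        assert list(table["label"]) == ["responder"]

    def test_marker_report_shape(self, fitted_fixture, fixture_bundle):
        report = marker_survival_report(
            fitted_fixture.panel_calls,
            fixture_bundle.clinical,
            ["GAPDH", "VIL1"],
            "baseline",
            endpoint="os",
        )
        # one row per marker per level
        assert len(report) == 4
        assert set(report["marker"]) == {"GAPDH", "VIL1"}
        assert set(report["level"]) == {"low", "high"}
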