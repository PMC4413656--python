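"""Kaplan–Meier, log-rank, score test and Cox fitting against closed forms
and independent implementations."""
import numpy as np
import pandas as pd
import pytest

import episcore as ep
from episcore.survival import _efron_loglik_grad_hess, fit_cox

from conftest import make_cohort, random_survival


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        km = ep.km_estimate([5, 8, 12], [0, 0, 0])
        assert km.survival_at(100) == 1.0
        assert not km.median_reached

    def test_closed_form_without_censoring(self):
        # all events at distinct times -> S is the empirical survival function
        km = ep.km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert km.survival_at(1) == pytest.approx(0.75)
        assert km.survival_at(2) == pytest.approx(0.5)
        assert km.median == pytest.approx(2.0)  # first time S <= 0.5

    def test_censoring_before_event_shrinks_risk_set_only(self):
        # censoring at t=1.5 leaves S unchanged there but the next event
        # removes 1/2 instead of 1/3 of the remaining curve
        km = ep.km_estimate([1, 1.5, 2, 3], [1, 0, 1, 1])
        assert km.survival_at(1.5) == pytest.approx(3 / 4)
        assert km.survival_at(2) == pytest.approx(3 / 8)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            ep.km_estimate([], [])

    def test_no_censoring_matches_empirical_survival(self, rng):
        t = rng.exponential(10, 200)
        km = ep.km_estimate(t, np.ones(200, int))
        for q in (5.0, 10.0, 20.0):
            assert km.survival_at(q) == pytest.approx((t > q).mean())


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([2.0, 4.0, 6.0, 8.0])
        e = np.array([1, 1, 0, 1])
        chi2, p = ep.logrank_test((t, e), (t, e))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_equals_cox_score_test_for_binary_group(self, rng):
        # classical equivalence, checked numerically to 1e-6 on tie-free data
        for _ in range(10):
            n = int(rng.integers(40, 120))
            x = (rng.random(n) > 0.5).astype(float)
            time, event = random_survival(rng, n, beta=rng.normal(0, 0.5), x=x)
            chi2_lr, _ = ep.logrank_test(
                (time[x == 0], event[x == 0]), (time[x == 1], event[x == 1])
            )
            chi2_sc, _ = ep.cox_score_test(x, time, event)
            assert chi2_lr == pytest.approx(chi2_sc, abs=1e-6)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="no subjects"):
            ep.logrank_test((np.array([1.0]), np.array([1])), (np.array([]), np.array([])))


class TestCox:
    def test_beta_is_log_of_hazard_ratio(self, rng):
        # a printed HR of 0.184 corresponds to beta = ln(0.184) ~ -1.693;
        # generate data at that effect and check the hr/beta contract exactly
        x = (rng.random(600) > 0.5).astype(float)
        time, event = random_survival(rng, 600, beta=np.log(0.184), x=x)
        fit = fit_cox(
            make_cohort(time, event, marker=x), ["marker"]
        )
        assert fit.hr("marker") == pytest.approx(np.exp(fit.beta("marker")), rel=1e-12)
        assert fit.beta("marker") == pytest.approx(np.log(0.184), abs=0.35)

    def test_null_covariate_beta_near_zero(self, rng):
        ps = []
        for _ in range(40):
            n = 80
            x = rng.permutation(np.repeat([0.0, 1.0], n // 2))
            time, event = random_survival(rng, n)
            fit = fit_cox(make_cohort(time, event, g=x), ["g"])
            ps.append(fit.p("g"))
        # Wald p roughly uniform: mean ~0.5, few very small
        assert 0.3 < np.mean(ps) < 0.7
        assert np.mean(np.array(ps) < 0.05) < 0.2

    def test_consistency_binary_effect(self, rng):
        x = (rng.random(2000) > 0.5).astype(float)
        time, event = random_survival(rng, 2000, beta=np.log(2), x=x,
                                      censor_scale=200.0)
        fit = fit_cox(make_cohort(time, event, g=x), ["g"])
        assert abs(fit.beta("g") - np.log(2)) < 0.1

    def test_efron_matches_independent_likelihood_oracle(self, rng):
        # the fitted beta maximizes the Efron partial likelihood: gradient
        # of an independently coded likelihood vanishes at the estimate
        n = 150
        x = rng.normal(size=n)
        time, event = random_survival(rng, n, beta=0.4, x=x)
        time = np.round(time, 0) + 0.5  # force ties
        fit = fit_cox(make_cohort(time, event, z=x), ["z"])
        # Newton-solve the independently coded Efron likelihood to high
        # precision and compare maximizers
        beta = np.zeros(1)
        for _ in range(50):
            _, grad, hess = _efron_loglik_grad_hess(beta, x[:, None], time, event)
            if abs(grad[0]) < 1e-10:
                break
            beta = beta - np.linalg.solve(hess, grad)
        assert fit.beta("z") == pytest.approx(beta[0], abs=1e-4)

    def test_efron_breslow_agree_without_ties(self, rng):
        n = 120
        x = rng.normal(size=n)
        time, event = random_survival(rng, n, beta=0.5, x=x)
        cohort = make_cohort(time, event, z=x)
        efron = fit_cox(cohort, ["z"], ties="efron")
        breslow = fit_cox(cohort, ["z"], ties="breslow")
        assert efron.beta("z") == pytest.approx(breslow.beta("z"), abs=1e-5)

    def test_separation_flagged_not_raised(self):
        # marker perfectly orders survival -> monotone likelihood
        time = np.arange(1.0, 21.0)
        event = np.ones(20, int)
        x = (time > 10).astype(float)
        fit = fit_cox(make_cohort(time, event, sep=x), ["sep"])
        assert not fit.converged
        assert np.isfinite(fit.beta("sep"))

    def test_constant_covariate_raises(self):
        with pytest.raises(ValueError, match="constant"):
            fit_cox(make_cohort([1, 2, 3], [1, 1, 1], c=[1.0, 1.0, 1.0]), ["c"])

    def test_wald_ci_covers_truth_reasonably(self, rng):
        cover = 0
        reps = 60
        for _ in range(reps):
            x = (rng.random(300) > 0.5).astype(float)
            time, event = random_survival(rng, 300, beta=np.log(2), x=x)
            fit = fit_cox(make_cohort(time, event, g=x), ["g"])
            lo, hi = fit.ci("g")
            cover += lo <= np.log(2) <= hi
        assert cover / reps > 0.85


class TestCoxTable:
    def _cohort(self, rng, n=300):
        x1 = (rng.random(n) > 0.5).astype(float)
        x2 = (rng.random(n) > 0.5).astype(float)
        lam = 0.02 * np.exp(np.log(2) * x1 + np.log(2) * x2)
        t_ev = rng.exponential(1 / lam)
        c = rng.uniform(0, 120, n)
        return make_cohort(
            np.minimum(t_ev, c), (t_ev <= c).astype(int), a=x1, b=x2
        )

    def test_uni_mode_matches_fit_cox(self, rng):
        cohort = self._cohort(rng)
        table = ep.cox_table(cohort, ["a", "b"], mode="uni")
        direct = fit_cox(cohort, ["a"])
        row = table[(table.fit_id == "a") & (table.covariate == "a")].iloc[0]
        assert row.beta == pytest.approx(direct.beta("a"), rel=1e-9)

    def test_bi_mode_independent_effects_both_significant(self, rng):
        cohort = self._cohort(rng)
        table = ep.cox_table(cohort, ["a", "b"], mode="bi")
        assert set(table.fit_id) == {"a+b"}
        assert table["significant"].all()

    def test_multi_mode_single_joint_fit(self, rng):
        cohort = self._cohort(rng)
        table = ep.cox_table(cohort, ["a", "b"], mode="multi")
        assert len(table) == 2 and set(table.fit_id) == {"a+b"}

    def test_collinear_covariates_flagged(self, rng):
        cohort = self._cohort(rng)
        cohort.df["a2"] = cohort.df["a"]
        table = ep.cox_table(cohort, ["a", "a2"], mode="multi")
        assert table["collinear"].all()

    def test_listwise_deletion_logged(self, rng, caplog):
        cohort = self._cohort(rng)
        cohort.df.loc[cohort.df.index[:10], "a"] = np.nan
        with caplog.at_level("INFO"):
            fit = fit_cox(cohort, ["a"])
        assert fit.n == len(cohort) - 10
        assert "listwise" in caplog.text
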