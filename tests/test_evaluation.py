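import numpy as np
import pytest
from sksurv.metrics import brier_score as sks_brier
from sksurv.util import Surv

from smoothlik import (AalenAdditive, CoxPH, GammaFrailtyPH, SmootherConfig,
                       StepFunction, SurvivalData, brier_score, cv_evaluate,
                       fit_cox, integrated_brier, kfold_split, km_censoring,
                       select_model)
from smoothlik.smoothing import smoothed_loglik
from conftest import make_cox_data


class TestKFoldSplit:
    def test_loo_special_case(self):
        folds = kfold_split(10, 10, 0)
        assert sorted(len(f) for f in folds) == [1] * 10

    def test_balanced_sizes(self):
        folds = kfold_split(10, 3, 0)
        assert sorted(len(f) for f in folds) == [3, 3, 4]
        assert np.array_equal(np.sort(np.concatenate(folds)), np.arange(10))

    def test_deterministic(self):
        a = kfold_split(50, 5, 7)
        b = kfold_split(50, 5, 7)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            kfold_split(5, 6, 0)
        with pytest.raises(ValueError):
            kfold_split(5, 1, 0)


class TestBrierScore:
    def test_perfect_predictions_no_censoring(self):
        data = SurvivalData([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        G = StepFunction(np.empty(0), np.empty(0), initial=1.0)
        t_star = 2.5
        S = (data.time > t_star).astype(float)
        assert brier_score(S, data, t_star, G) == 0.0

    def test_constant_half_no_censoring(self):
        data = SurvivalData([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        G = StepFunction(np.empty(0), np.empty(0), initial=1.0)
        assert brier_score(np.full(4, 0.5), data, 2.5, G) == \
            pytest.approx(0.25)

    def test_hand_computed_ipcw_toy(self):
        # train: times (1,2,3,4), delta (0,1,0,1) -> G(1)=3/4, G(3)=3/8
        train = SurvivalData([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 1])
        G = km_censoring(train)
        test = SurvivalData([1.5, 2.5, 3.5, 5.0], [1, 0, 1, 0])
        S = np.array([0.9, 0.8, 0.4, 0.2])
        t_star = 3.6
        # subj 1: event at 1.5 <= t*: w=1/G(1.5-)=1/G(1)=4/3, c=w*0.9^2
        # subj 2: censored at 2.5 < t*: contributes 0
        # subj 3: event at 3.5 <= t*: w=1/G(3.5-)=1/(3/8)=8/3, c=w*0.4^2
        # subj 4: at risk at t*: w=1/G(3.6)=8/3, c=w*(1-0.2)^2
        expected = (4 / 3 * 0.81 + 8 / 3 * 0.16 + 8 / 3 * 0.64) / 4
        assert brier_score(S, test, t_star, G) == pytest.approx(expected)

    def test_matches_scikit_survival(self):
        train = make_cox_data(21, n=80)
        test = make_cox_data(22, n=40)
        fit = fit_cox(train)
        t_star = float(np.median(train.time))
        S = fit.survival_at(test.X, np.full(test.n, t_star))
        mine = brier_score(S, test, t_star, km_censoring(train))
        _, theirs = sks_brier(
            Surv.from_arrays(train.event.astype(bool), train.time),
            Surv.from_arrays(test.event.astype(bool), test.time),
            S, [t_star])
        assert mine == pytest.approx(theirs[0], abs=1e-12)


class TestIntegratedBrier:
    def test_perfect_predictions_zero(self):
        data = SurvivalData([1.0, 2.0, 3.0], [1, 1, 1])
        G = StepFunction(np.empty(0), np.empty(0), initial=1.0)
        curves = [StepFunction([t], [-1.0], initial=1.0) for t in data.time]
        grid = np.array([0.5, 1.5, 2.5, 3.5])
        assert integrated_brier(curves, data, G, grid) == 0.0

    def test_constant_half_integrand(self):
        data = SurvivalData([10.0, 11.0, 12.0], [1, 1, 1])
        G = StepFunction(np.empty(0), np.empty(0), initial=1.0)
        curves = [StepFunction(np.empty(0), np.empty(0), initial=0.5)
                  for _ in range(3)]
        grid = np.linspace(1.0, 9.0, 9)
        # integrand is 0.25 everywhere except the t=0 endpoint
        val = integrated_brier(curves, data, G, grid)
        assert val == pytest.approx(0.25 * (9.0 - 0.5 * 1.0) / 9.0, rel=1e-6)

    def test_against_dense_grid_quadrature(self):
        train = make_cox_data(31, n=60)
        test = make_cox_data(32, n=30)
        fit = fit_cox(train)
        G = km_censoring(train)
        curves = fit.predict_survival_function(test.X)
        coarse = integrated_brier(curves, test, G, fit.event_times_)
        t_max = fit.event_times_[-1]
        dense = np.union1d(fit.event_times_,
                           np.linspace(1e-6, t_max, 4000))
        fine = integrated_brier(curves, test, G, dense)
        # the event-time grid misses indicator flips at test times between
        # grid points; agreement is up to that quadrature error
        assert coarse == pytest.approx(fine, rel=0.05)


class TestCVEvaluate:
    def test_result_bookkeeping(self, cox_data):
        res = cv_evaluate(CoxPH(), cox_data.X, cox_data.y,
                          losses="smoothed_loglik", K=5, seed=1)
        assert res.total == pytest.approx(res.per_subject.sum())
        assert res.total == pytest.approx(res.per_fold_sum.sum())
        assert res.K == 5 and res.direction == "higher"

    def test_deterministic_given_seed(self, cox_data):
        a = cv_evaluate(CoxPH(), cox_data.X, cox_data.y, K=5, seed=3)
        b = cv_evaluate(CoxPH(), cox_data.X, cox_data.y, K=5, seed=3)
        np.testing.assert_array_equal(a.per_subject, b.per_subject)

    def test_loo_equals_kfold_with_n_folds(self, cox_data):
        res = cv_evaluate(CoxPH(), cox_data.X, cox_data.y, K=cox_data.n,
                          seed=0)
        assert res.K == cox_data.n
        assert all(len(f) == 1 for f in
                   [np.flatnonzero(res.fold_index == k)
                    for k in range(res.K)])

    def test_cvpl_requires_cox(self, cox_data):
        with pytest.raises(ValueError):
            cv_evaluate(GammaFrailtyPH(), cox_data.X, cox_data.y,
                        losses="cvpl", K=5, seed=0)

    def test_matches_naive_reimplementation(self):
        # independent end-to-end loop: fit per fold, smooth per subject
        data = make_cox_data(41, n=40)
        K, seed = 4, 9
        folds = kfold_split(data.n, K, seed)
        cfg = SmootherConfig()
        res = cv_evaluate(CoxPH(), data.X, data.y,
                          losses="smoothed_loglik", folds=folds,
                          smoother=cfg)
        naive = np.zeros(data.n)
        for te in folds:
            tr = np.setdiff1d(np.arange(data.n), te)
            fit = fit_cox(data.subset(tr))
            for i in te:
                H = fit.predict_cumulative_hazard(data.covariates[[i]])[0]
                naive[i] = smoothed_loglik(H, data.time[i],
                                           int(data.event[i]), cfg,
                                           fit.event_times_)
        np.testing.assert_allclose(res.per_subject, naive, atol=1e-10)

    def test_no_leakage_across_test_mates(self):
        # perturbing other test-fold members leaves a subject's loss intact
        data = make_cox_data(43, n=40)
        folds = [np.arange(0, 20), np.arange(20, 40)]
        res1 = cv_evaluate(CoxPH(), data.X, data.y, folds=folds,
                          losses="smoothed_loglik")
        cov2 = data.covariates.copy()
        cov2[1:20] = cov2[1:20][::-1]
        time2, ev2 = data.time.copy(), data.event.copy()
        time2[1:20] = time2[1:20][::-1]
        ev2[1:20] = ev2[1:20][::-1]
        res2 = cv_evaluate(CoxPH(), cov2, (time2, ev2), folds=folds,
                           losses="smoothed_loglik")
        assert res1.per_subject[0] == res2.per_subject[0]

    def test_all_losses_on_all_models(self, cox_data):
        for est in [CoxPH(), GammaFrailtyPH(), AalenAdditive(1.0)]:
            res = cv_evaluate(est, cox_data.X, cox_data.y,
                              losses=["smoothed_loglik", "brier", "ibs"],
                              K=4, seed=2)
            for r in res.values():
                assert np.isfinite(r.total)


class TestSelectModel:
    def _result(self, per_subject, direction="higher"):
        n = len(per_subject)
        from smoothlik.evaluation import CVResult
        return CVResult(loss="smoothed_loglik",
                        per_subject=np.asarray(per_subject, float),
                        fold_index=np.arange(n) % 2, K=2, seed=0,
                        direction=direction)

    def test_single_candidate_wins_both_rules(self):
        res = {"a": self._result([1.0, 2.0])}
        report = select_model(res, {"a": 0})
        assert report.winner_min == "a" and report.winner_1se == "a"

    def test_one_se_prefers_parsimony(self):
        # A totals -95 (fold SE 5); B totals -98 with fewer covariates:
        # min-rule keeps A, the one-SE rule backs off to B
        a = self._result([-50.0, -45.0])
        b = self._result([-49.0, -49.0])
        assert a.fold_se == pytest.approx(5.0)
        report = select_model({"A": a, "B": b}, {"A": 2, "B": 1})
        assert report.winner_min == "A"
        assert report.winner_1se == "B"

    def test_exact_tie_broken_by_parsimony(self):
        a = self._result([-10.0, -10.0])
        b = self._result([-10.0, -10.0])
        report = select_model({"A": a, "B": b}, {"A": 2, "B": 1})
        assert report.winner_min == "B"

    def test_lower_is_better_direction(self):
        a = self._result([0.2, 0.2], direction="lower")
        b = self._result([0.3, 0.3], direction="lower")
        report = select_model({"A": a, "B": b}, {"A": 1, "B": 0})
        assert report.winner_min == "A"

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_model({}, {})
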