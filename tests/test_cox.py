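import numpy as np
import pytest
from lifelines import CoxPHFitter

from smoothlik import (CoxPH, SurvivalData, cvpl_contributions, cvpl_verweij,
                       fit_cox, partial_loglik, predict_cumhaz, warp_time)
from smoothlik.cox import ConvergenceError, _newton, _prepare
from conftest import make_cox_data


def naive_partial_loglik(data, beta):
    """Brute-force Breslow partial likelihood, rebuilding every risk set."""
    beta = np.atleast_1d(np.asarray(beta, float))
    ll = 0.0
    for j in range(data.n):
        if data.event[j] != 1:
            continue
        risk = data.time >= data.time[j]
        ll += data.covariates[j] @ beta
        ll -= np.log(np.exp(data.covariates[risk] @ beta).sum())
    return ll


class TestPartialLoglik:
    def test_two_subject_closed_form_at_zero(self):
        data = SurvivalData([1.0, 2.0], [1, 1], np.array([1.0, 0.0]))
        assert partial_loglik(data, [0.0]) == pytest.approx(-np.log(2.0))

    @pytest.mark.parametrize("beta", [-1.3, -0.2, 0.0, 0.7, 2.1])
    def test_two_subject_closed_form_general(self, beta):
        data = SurvivalData([1.0, 2.0], [1, 1], np.array([1.0, 0.0]))
        expected = beta - np.log(np.exp(beta) + 1.0)
        assert partial_loglik(data, [beta]) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_risk_set_oracle(self, seed):
        data = make_cox_data(seed, n=5 + seed)
        rng = np.random.default_rng(seed)
        beta = rng.normal(size=2)
        assert partial_loglik(data, beta) == pytest.approx(
            naive_partial_loglik(data, beta), abs=1e-10)

    def test_dimension_mismatch(self, cox_data):
        with pytest.raises(ValueError):
            partial_loglik(cox_data, [0.1, 0.2, 0.3])

    @pytest.mark.parametrize("g", [lambda t: t ** 2, lambda t: np.log1p(t)])
    def test_warp_invariance_exact(self, cox_data, g):
        beta = [0.4, -0.2]
        assert partial_loglik(cox_data, beta) == \
            partial_loglik(warp_time(cox_data, g), beta)


class TestFitCox:
    def test_sign_flip_symmetry(self, cox_data):
        plus = fit_cox(cox_data)
        flipped = SurvivalData(cox_data.time, cox_data.event,
                               -cox_data.covariates)
        minus = fit_cox(flipped)
        np.testing.assert_allclose(plus.coef_, -minus.coef_, atol=1e-9)

    def test_matches_lifelines(self):
        data = make_cox_data(7, n=120)
        fit = fit_cox(data)
        cph = CoxPHFitter().fit(data.to_frame(), duration_col="time",
                                event_col="event")
        np.testing.assert_allclose(fit.coef_, cph.params_.values, atol=1e-5)
        # Breslow cumulative baseline agrees at the event times (lifelines
        # reports the baseline at the covariate mean, not at x = 0)
        ll_base = cph.baseline_cumulative_hazard_
        shift = float(np.exp(data.covariates.mean(axis=0) @ fit.coef_))
        mine = fit.baseline_hazard_.cumulative * shift
        theirs = np.interp(fit.event_times_, ll_base.index.values,
                           ll_base.iloc[:, 0].values)
        np.testing.assert_allclose(mine, theirs, rtol=1e-4)

    def test_grid_maximization_oracle(self):
        data = make_cox_data(3, n=30, beta=(0.8,))
        fit = fit_cox(data)
        grid = np.arange(-3.0, 3.0, 0.01)
        values = [naive_partial_loglik(data, [b]) for b in grid]
        assert abs(fit.coef_[0] - grid[int(np.argmax(values))]) <= 0.01

    def test_baseline_is_nelson_aalen_at_beta_zero(self):
        # pure-noise covariate scaled to 0 -> beta-hat = 0 -> NA increments
        data = make_cox_data(5, n=40)
        data = SurvivalData(data.time, data.event,
                            np.zeros_like(data.covariates))
        fit = fit_cox(data)
        at_risk = np.array([(data.time >= t).sum()
                            for t in fit.event_times_])
        np.testing.assert_allclose(fit.baseline_hazard_.increments,
                                   1.0 / at_risk, atol=1e-12)

    def test_breslow_risk_weight_identity(self, cox_data):
        # sum of risk-set weights times the increment is 1 at each event time
        fit = fit_cox(cox_data)
        w = np.exp(cox_data.covariates @ fit.coef_)
        for t, lam in zip(fit.event_times_, fit.baseline_hazard_.increments):
            assert w[cox_data.time >= t].sum() * lam == pytest.approx(1.0)

    def test_coefficient_recovery(self):
        # mean of beta-hat over replicates within 3 MC SEs of the truth
        est = [fit_cox(make_cox_data(1000 + r, n=2000, beta=(0.8,),
                                     censor_scale=3.0)).coef_[0]
               for r in range(6)]
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - 0.8) < 3 * se + 1e-9

    def test_coefficient_table_writer(self, tmp_path, cox_data):
        import pandas as pd
        from smoothlik.cox import write_coefficients_csv
        fit = fit_cox(cox_data)
        path = tmp_path / "coefs.csv"
        write_coefficients_csv(fit, path, names=cox_data.covariate_names)
        df = pd.read_csv(path)
        assert list(df.columns) == ["name", "estimate"]
        np.testing.assert_allclose(df["estimate"], fit.coef_)

    def test_no_events_rejected(self):
        data = SurvivalData([1.0, 2.0], [0, 0], np.array([1.0, -1.0]))
        with pytest.raises(ValueError):
            fit_cox(data)

    def test_separation_raises_convergence_error(self):
        # perfectly separating covariate -> monotone likelihood
        data = SurvivalData([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1],
                            np.array([1.0, 0.5, -0.5, -1.0]))
        with pytest.raises(ConvergenceError) as err:
            fit_cox(data)
        assert err.value.last_iterate is not None


class TestPredictCumhaz:
    def test_zero_covariates_return_baseline(self, cox_data):
        fit = fit_cox(cox_data)
        H = predict_cumhaz(fit, np.zeros(2))
        np.testing.assert_allclose(H.increments,
                                   fit.baseline_hazard_.increments)

    def test_proportionality(self, cox_data):
        fit = fit_cox(cox_data)
        x = np.array([0.3, -0.1])
        H1 = predict_cumhaz(fit, x)
        shift = np.log(2.0) / fit.coef_[0]
        H2 = predict_cumhaz(fit, x + np.array([shift, 0.0]))
        np.testing.assert_allclose(H2.increments, 2.0 * H1.increments,
                                   rtol=1e-9)

    def test_survival_curve_monotone(self, cox_data):
        fit = fit_cox(cox_data)
        S = fit.predict_survival_function(cox_data.X[:3])[0]
        vals = S(np.linspace(0, cox_data.time.max(), 50))
        assert np.all(np.diff(vals) <= 1e-15)

    def test_dimension_mismatch(self, cox_data):
        fit = fit_cox(cox_data)
        with pytest.raises(ValueError):
            predict_cumhaz(fit, np.zeros(5))


def literal_loo_cvpl(data):
    """Literal two-evaluation oracle: pl(beta(-i)) - pl^(-i)(beta(-i))."""
    out = np.empty(data.n)
    for i in range(data.n):
        keep = np.setdiff1d(np.arange(data.n), [i])
        sub = data.subset(keep)
        prep = _prepare(sub.time, sub.event, sub.covariates)
        beta, _, _ = _newton(prep)
        out[i] = naive_partial_loglik(data, beta) - \
            naive_partial_loglik(sub, beta)
    return out


def augmented_baseline_loglik(data, i):
    """Predictive log-likelihood with the augmented-risk-set baseline.

    Baseline increments at the training event times use risk sets that
    include subject i; the cumulative hazard sums those increments up to
    T_i.  Equals the CVPL contribution up to second order in the per-event
    quantities w_i * h0_tilde.
    """
    keep = np.setdiff1d(np.arange(data.n), [i])
    sub = data.subset(keep)
    prep = _prepare(sub.time, sub.event, sub.covariates)
    beta, _, _ = _newton(prep)
    w_all = np.exp(data.covariates @ beta)
    t_i, d_i, w_i = data.time[i], data.event[i], w_all[i]
    ev_times = np.sort(sub.time[sub.event == 1])
    lam = np.array([1.0 / w_all[data.time >= t].sum() for t in ev_times])
    H = w_i * lam[ev_times <= t_i].sum()
    ell = -H
    if d_i:
        own = 1.0 / w_all[data.time >= t_i].sum()
        ell += np.log(w_i * own)
    # second-order bound sum_j u_j^2 / 2 with u_j = w_i / S_j the ratio of
    # the subject's weight to the UNaugmented training risk-set sum
    x = w_i * lam[ev_times <= t_i]
    u = x / (1.0 - x)
    return ell, 0.5 * (u ** 2).sum()


class TestCVPL:
    def test_loo_matches_literal_oracle(self):
        data = make_cox_data(11, n=10)
        mine = cvpl_contributions(data)
        oracle = literal_loo_cvpl(data)
        np.testing.assert_allclose(mine, oracle, atol=1e-10)

    def test_subject_censored_before_first_event_contributes_zero(self):
        data = make_cox_data(13, n=20)
        first_event = data.event_times[0]
        time = data.time.copy()
        event = data.event.copy()
        time[0], event[0] = first_event / 2.0, 0
        data = SurvivalData(time, event, data.covariates)
        folds = [np.array([0]), np.arange(1, 11), np.arange(11, 20)]
        contrib = cvpl_contributions(data, folds)
        assert contrib[0] == 0.0

    def test_contributions_approximate_augmented_baseline_loglik(self):
        data = make_cox_data(17, n=30)
        mine = cvpl_contributions(data)
        for i in range(data.n):
            ell, bound = augmented_baseline_loglik(data, i)
            assert abs(mine[i] - ell) <= bound + 1e-10

    @pytest.mark.parametrize("g", [lambda t: t ** 2, lambda t: np.log1p(t)])
    def test_warp_invariance_exact(self, g):
        data = make_cox_data(19, n=25)
        assert cvpl_verweij(data) == cvpl_verweij(warp_time(data, g))

    def test_kfold_contribution_independent_of_test_mates(self):
        # a subject's contribution only depends on the training fold
        data = make_cox_data(23, n=30)
        folds = [np.arange(0, 10), np.arange(10, 30)]
        c1 = cvpl_contributions(data, folds)
        perm = data.covariates.copy()
        perm[1:10] = perm[1:10][::-1]       # shuffle other fold-members
        shuffled = SurvivalData(data.time, data.event, perm)
        c2 = cvpl_contributions(shuffled, folds)
        assert c1[0] == c2[0]

    def test_fold_without_training_events_rejected(self):
        data = SurvivalData([1.0, 2.0, 3.0], [1, 0, 0],
                            np.array([0.1, -0.2, 0.3]))
        with pytest.raises(ValueError):
            cvpl_contributions(data, [np.array([0]), np.array([1, 2])])
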