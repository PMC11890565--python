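"""Elastic-net Cox: closed forms, optimality certificates, oracle
equivalences, bootstrap tuning contracts and the training workflow."""

import warnings

import numpy as np
import pandas as pd
import pytest

from tnbcprog._survival import newton_cox
from tnbcprog.coxnet import (
    FittedCoxnetModel,
    TuningGrid,
    bootstrap_oob_tune,
    cox_deviance,
    cox_partial_loglik,
    fit_coxnet,
    kkt_max_violation,
    risk_score,
    train_prognostic_model,
)
from tnbcprog.features import FeatureMatrix
from tnbcprog.stats import cox_univariate
from tnbcprog.synthetic import simulate_survival


def _sim(seed, n=120, p=8, beta=None, shape=1.1, scale=10.0, window=12.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if beta is None:
        beta = np.zeros(p)
        beta[: min(3, p)] = [0.6, -0.6, 0.4][: min(3, p)]
    t, e = simulate_survival(X @ beta, shape, scale, window, rng)
    return X, t, e


class TestClosedForms:
    def test_loglik_at_zero_is_minus_sum_log_risk_sets(self):
        X = np.zeros((3, 1))
        t, e = np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1])
        expect = -(np.log(3) + np.log(2) + np.log(1))
        assert cox_partial_loglik(np.zeros(1), X, t, e) == pytest.approx(expect, abs=1e-12)

    def test_n4_loglik_matches_term_by_term_hand_enumeration(self):
        x = np.array([0.5, -1.0, 2.0, 0.0])
        t = np.array([2.0, 1.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 1])
        b = 0.7
        r = np.exp(b * x)
        # events at t=1 (all 4 at risk), t=2 (x0,x2,x3), t=4 (x3)
        expect = (
            (b * x[1] - np.log(r.sum()))
            + (b * x[0] - np.log(r[0] + r[2] + r[3]))
            + (b * x[3] - np.log(r[3]))
        )
        got = cox_partial_loglik(np.array([b]), x[:, None], t, e)
        assert got == pytest.approx(expect, abs=1e-12)

    def test_all_censored_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="no events"):
            assert cox_partial_loglik(np.zeros(1), np.zeros((3, 1)), [1, 2, 3], [0, 0, 0]) == 0.0

    def test_deviance_hand_example_and_no_event_case(self):
        X = np.zeros((2, 1))
        assert cox_deviance(np.zeros(1), X, [1.0, 2.0], [1, 1]) == pytest.approx(
            2 * np.log(2), abs=1e-12
        )
        assert cox_deviance(np.zeros(1), X, [1.0, 2.0], [0, 0]) == 0.0

    def test_deviance_with_ties_uses_saturated_term(self):
        # two events tied at t=1 among n=3: ll_sat = -2 log 2
        X = np.array([[0.0], [0.0], [0.0]])
        dev = cox_deviance(np.zeros(1), X, [1.0, 1.0, 2.0], [1, 1, 0])
        ll0 = -2 * np.log(3)  # each tied event sees the full risk set of 3
        ll_sat = -2 * np.log(2)
        assert dev == pytest.approx(2 * (ll_sat - ll0), abs=1e-12)

    def test_deviance_at_fit_no_greater_than_at_zero(self):
        X, t, e = _sim(0)
        fit = fit_coxnet(X, t, e, 0.5, 0.05)
        assert cox_deviance(fit.beta, X, t, e) <= cox_deviance(np.zeros(X.shape[1]), X, t, e)


class TestFitCoxnet:
    def test_huge_lambda_gives_exactly_zero(self):
        X, t, e = _sim(1)
        fit = fit_coxnet(X, t, e, 0.5, 1e4)
        assert np.all(fit.beta == 0.0)

    def test_lambda_zero_matches_newton_oracle(self):
        X, t, e = _sim(2, n=200, p=5)
        fit = fit_coxnet(X, t, e, 0.5, 0.0)
        oracle = newton_cox(X, t, e)
        np.testing.assert_allclose(fit.beta, oracle.beta, atol=1e-4)

    def test_lasso_entry_threshold_from_kkt_condition(self):
        X, t, e = _sim(3, n=150, p=6)
        n = X.shape[0]
        Xs = (X - X.mean(0)) / X.std(0)
        from tnbcprog._survival import CoxData

        g, _ = CoxData(t, e).eta_grad_diag_hess(np.zeros(n))
        lam_max = np.max(np.abs(Xs.T @ g)) / n
        assert np.all(fit_coxnet(X, t, e, 1.0, lam_max * 1.001).beta == 0.0)
        assert np.sum(fit_coxnet(X, t, e, 1.0, lam_max * 0.95).beta != 0) >= 1

    @pytest.mark.parametrize("alpha", [0.3, 1.0])
    def test_kkt_certificate_on_random_instances(self, alpha):
        rng = np.random.default_rng(7)
        for _ in range(15):
            n = int(rng.integers(40, 100))
            p = int(rng.integers(3, 20))
            X, t, e = _sim(int(rng.integers(1 << 30)), n=n, p=p)
            lam = float(10 ** rng.uniform(-2, 0))
            fit = fit_coxnet(X, t, e, alpha, lam)
            assert kkt_max_violation(fit, X, t, e) < 1e-5

    def test_warm_and_cold_start_solutions_agree(self):
        X, t, e = _sim(5, n=90, p=15)
        from tnbcprog._survival import CoxData
        from tnbcprog.coxnet import _fit_path

        Xs = (X - X.mean(0)) / X.std(0)
        cox = CoxData(t, e)
        lams = np.logspace(0.5, -1.5, 8)
        warm = _fit_path(Xs, cox, 0.5, lams, 1e-7, 1000)
        for lam, bw in zip(lams, warm):
            cold = fit_coxnet(X, t, e, 0.5, lam)
            np.testing.assert_allclose(bw, cold.beta_std, atol=1e-6)

    def test_scaled_coef_is_original_times_sd_and_rank_equivalent(self):
        X, t, e = _sim(6)
        fit = fit_coxnet(X, t, e, 0.5, 0.05)
        np.testing.assert_allclose(fit.beta * fit.sd, fit.beta_std, atol=1e-12)
        r1 = X @ fit.beta
        r2 = ((X - fit.mean) / fit.sd) @ fit.beta_std
        np.testing.assert_allclose(np.argsort(r1), np.argsort(r2))

    def test_zero_variance_column_rejected(self):
        X, t, e = _sim(7)
        X[:, 0] = 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            fit_coxnet(X, t, e, 0.5, 0.1)

    def test_invalid_hyperparameters_rejected(self):
        X, t, e = _sim(8)
        with pytest.raises(ValueError):
            fit_coxnet(X, t, e, 0.0, 0.1)
        with pytest.raises(ValueError):
            fit_coxnet(X, t, e, 0.5, -1.0)

    def test_matches_scikit_survival_reference(self):
        """Independent cross-check against a published coxnet solver."""
        sksurv = pytest.importorskip("sksurv.linear_model")
        X, t, e = _sim(9, n=150, p=10)
        Xs = (X - X.mean(0)) / X.std(0)
        y = np.array(
            [(bool(ei), ti) for ei, ti in zip(e, t)],
            dtype=[("event", "?"), ("time", "<f8")],
        )
        lam = 0.08
        ref = sksurv.CoxnetSurvivalAnalysis(
            alphas=[lam], l1_ratio=0.5, normalize=False, fit_baseline_model=False,
            tol=1e-9,
        ).fit(Xs, y)
        fit = fit_coxnet(Xs, t, e, 0.5, lam)
        np.testing.assert_allclose(ref.coef_[:, 0], fit.beta_std, atol=2e-3)


class TestBootstrapTune:
    def test_single_point_grid_returned(self):
        X, t, e = _sim(10, n=80, p=5)
        grid = TuningGrid(alphas=(0.5,), lambdas=(0.3,))
        res = bootstrap_oob_tune(X, t, e, grid=grid, B=5, seed=1)
        assert res.alpha == 0.5 and res.lam == 0.3
        assert res.deviance_table.shape == (5, 1)

    def test_same_seed_identical_results(self):
        X, t, e = _sim(11, n=80, p=5)
        grid = TuningGrid(alphas=(0.3, 0.7), lambdas=(1.0, 0.1))
        a = bootstrap_oob_tune(X, t, e, grid=grid, B=8, seed=4)
        b = bootstrap_oob_tune(X, t, e, grid=grid, B=8, seed=4)
        assert (a.alpha, a.lam) == (b.alpha, b.lam)
        pd.testing.assert_frame_equal(a.deviance_table, b.deviance_table)

    def test_growing_b_preserves_earlier_resamples(self):
        X, t, e = _sim(12, n=80, p=5)
        grid = TuningGrid(alphas=(0.5,), lambdas=(0.5,))
        small = bootstrap_oob_tune(X, t, e, grid=grid, B=4, seed=9)
        big = bootstrap_oob_tune(X, t, e, grid=grid, B=8, seed=9)
        pd.testing.assert_frame_equal(big.deviance_table.iloc[:4], small.deviance_table)

    def test_too_few_events_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(ValueError, match="two events"):
            bootstrap_oob_tune(X, np.arange(1.0, 21.0), np.zeros(20), B=3, seed=0)


def _feature_matrix(X, prefix, category):
    cols = [f"{prefix}{j}" for j in range(X.shape[1])]
    vals = pd.DataFrame(X, columns=cols)
    return FeatureMatrix(values=vals, category=pd.Series(category, index=cols))


class TestTrainWorkflow:
    def test_clinical_only_bypasses_regularization(self):
        rng = np.random.default_rng(21)
        stage = (rng.uniform(size=300) < 0.3).astype(float)
        t, e = simulate_survival(0.6 * stage, 1.1, 10.0, 12.0, rng)
        fm = FeatureMatrix(
            values=pd.DataFrame({"stage": stage}),
            category=pd.Series({"stage": "clinical"}),
        )
        model = train_prognostic_model(fm, t, e, ("clinical",), B=5, seed=0)
        assert not model.penalized
        ref = cox_univariate(t, e, stage)
        assert model.coef["stage"] == pytest.approx(np.log(ref.estimate), abs=1e-8)

    def test_pure_noise_may_select_nothing_and_is_flagged_valid(self):
        rng = np.random.default_rng(22)
        X = rng.binomial(1, 0.3, size=(150, 30)).astype(float)
        t, e = simulate_survival(np.zeros(150), 1.1, 10.0, 12.0, rng)
        fm = _feature_matrix(X, "mut:", "gene_mutation")
        grid = TuningGrid(alphas=(0.5,), lambdas=(10.0, 1.0))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = train_prognostic_model(fm, t, e, ("dna",), grid=grid, B=5, seed=1)
        if model.is_empty:
            assert any("no features" in str(w.message) for w in caught)
            scores = risk_score(model, fm.values)
            assert (scores == 0).all()

    def test_recovered_signs_match_planted_effects(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(400, 40))
        beta = np.zeros(40)
        beta[:4] = [0.8, -0.8, 0.7, -0.7]
        t, e = simulate_survival(X @ beta, 1.1, 10.0, 15.0, rng)
        fm = _feature_matrix(X, "sig:", "rna_signature")
        grid = TuningGrid(alphas=(0.5, 0.9), lambdas=tuple(np.logspace(0.5, -1, 6)))
        model = train_prognostic_model(fm, t, e, ("rna",), grid=grid, B=10, seed=2)
        for j in range(4):
            c = model.coef[f"sig:{j}"]
            assert c == 0 or np.sign(c) == np.sign(beta[j])
        assert sum(model.coef[f"sig:{j}"] != 0 for j in range(4)) >= 3

    def test_model_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(24)
        X = rng.normal(size=(100, 6))
        t, e = simulate_survival(X[:, 0] * 0.5, 1.1, 10.0, 12.0, rng)
        fm = _feature_matrix(X, "sig:", "rna_signature")
        grid = TuningGrid(alphas=(0.5,), lambdas=(0.3, 0.05))
        model = train_prognostic_model(fm, t, e, ("rna",), grid=grid, B=5, seed=3)
        path = tmp_path / "m.json"
        model.to_json(path)
        back = FittedCoxnetModel.from_json(path)
        pd.testing.assert_series_equal(model.coef, back.coef)
        assert back.alpha == model.alpha and back.lam == model.lam


class TestRiskScore:
    def _model(self, coef):
        idx = pd.Index(list(coef))
        return FittedCoxnetModel(
            alpha=0.5,
            lam=0.1,
            coef=pd.Series(coef),
            scaled_coef=pd.Series(coef),
            feature_mean=pd.Series(0.0, index=idx),
            feature_sd=pd.Series(1.0, index=idx),
            categories=("rna",),
            seed=0,
        )

    def test_hand_matrix_product(self):
        model = self._model({"a": 2.0, "b": -1.0})
        X = pd.DataFrame({"a": [1.0, 0.0, 3.0], "b": [1.0, 2.0, 0.0]})
        np.testing.assert_allclose(risk_score(model, X), [1.0, -2.0, 6.0])

    def test_single_feature_equals_that_feature(self):
        model = self._model({"a": 1.0})
        X = pd.DataFrame({"a": [0.3, 0.7]})
        np.testing.assert_allclose(risk_score(model, X), X["a"])

    def test_empty_model_scores_zero_and_missing_column_errors(self):
        empty = self._model({"a": 0.0})
        X = pd.DataFrame({"q": [1.0]})
        assert (risk_score(empty, X) == 0).all()
        full = self._model({"a": 1.0})
        with pytest.raises(KeyError, match="missing"):
            risk_score(full, X)
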