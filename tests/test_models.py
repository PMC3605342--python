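"""Basis construction, PLS LOSO-CV, stepwise OLS, and diagnostics."""

import numpy as np
import pandas as pd
import pytest

import anklemech as am
from anklemech.models import DegenerateModelError, Term
from anklemech.types import DomainError, JointSummary, SubjectProfile


def make_summary(sid="S01", speed=1.5, g_df=0.2, g_dl=0.05, g_pf=0.48, **kw):
    base = dict(
        subject_id=sid, speed=speed, K_df=250.0, K_dl=1000.0, K_pf=200.0,
        Gamma_df=g_df, Gamma_dl=abs(g_dl), Gamma_pf=g_pf, Gamma_dl_signed=g_dl,
        r2_df=0.96, r2_dl=0.75, r2_pf=0.93, E_loop=17.0, E_fit=17.0,
    )
    base.update(kw)
    return JointSummary(**base)


def make_subject(sid="S01", W=70.0, H=1.7):
    return SubjectProfile(sid, W, H, preferred_speed=1.4, singular_speed=1.8)


class TestBasis:
    def test_term_arithmetic(self):
        t1 = Term(w=1, h=1, phase="df", g_exp=-1)
        t2 = Term(w=1, h=1, v=1, phase="df", g_exp=-1)
        gam = {"df": 0.2}
        assert t1.evaluate(70, 1.7, 1.5, gam) == pytest.approx(595.0)
        assert t2.evaluate(70, 1.7, 1.5, gam) == pytest.approx(892.5)

    def test_work_basis_has_nine_columns(self):
        spec = am.default_basis("E")
        assert len(spec.all_terms) == 9
        assert not spec.include_intercept

    def test_stiffness_bases_sizes(self):
        assert len(am.default_basis("K_df").all_terms) == 5
        assert len(am.default_basis("K_dl").all_terms) == 8
        assert len(am.default_basis("K_pf").all_terms) == 8

    def test_empty_summaries_give_empty_matrix(self):
        X, y, groups, dropped = am.build_basis([], [], am.default_basis("K_df"))
        assert X.shape == (0, 5) and len(y) == 0 and dropped == []

    def test_singular_rows_dropped_for_dual_response(self):
        subj = make_subject()
        rows = [make_summary(), make_summary(speed=1.8, singular=True)]
        X, y, groups, dropped = am.build_basis(rows, [subj], am.default_basis("K_dl"))
        assert len(y) == 1
        assert dropped == [(1, "singular dual-flexion trial")]

    def test_unknown_subject_rejected(self):
        with pytest.raises(DomainError):
            am.build_basis([make_summary(sid="??")], [make_subject()],
                           am.default_basis("K_df"))


class TestPlsLosoCv:
    def test_exact_rank_one_design(self):
        # one latent direction drives both X and y, with no noise
        rng = np.random.default_rng(0)
        t = rng.normal(size=100)
        X = np.outer(t, rng.normal(size=5))
        y = 3.0 * t
        groups = np.repeat(np.arange(10), 10)
        out = am.pls_loso_cv(X, y, groups)
        assert out["n_components"] == 1
        assert out["r2"] == pytest.approx(100.0, abs=1e-6)
        assert out["predicted_r2"] == pytest.approx(100.0, abs=1e-6)

    def test_latent_rank_three_recovered(self):
        rng = np.random.default_rng(3)
        n, p, r = 200, 8, 3
        T = rng.normal(size=(n, r))
        P = rng.normal(size=(r, p))
        X = T @ P + 1e-3 * rng.normal(size=(n, p))
        y = T @ np.array([3.0, -2.0, 1.5]) + 0.5 * rng.normal(size=n)
        groups = np.repeat(np.arange(20), 10)
        out = am.pls_loso_cv(X, y, groups)
        assert out["n_components"] == 3
        assert out["predicted_r2"] <= out["r2"] + 1e-9

    def test_single_group_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(DomainError):
            am.pls_loso_cv(X, X[:, 0], np.zeros(20))


class TestStepwiseOLS:
    def test_true_support_recovered(self):
        rng = np.random.default_rng(0)
        n = 500
        X = pd.DataFrame(
            rng.normal(size=(n, 5)), columns=[f"t{i}" for i in range(5)]
        )
        y = 4.0 * X["t1"] - 2.5 * X["t3"]
        y = y * (1 + 0.01 * rng.normal(size=n))
        model = am.stepwise_ols(X, y, alpha=0.05)
        assert model.retained_ == ["t1", "t3"]
        coefs = dict(zip(model.retained_, model.coef_))
        assert coefs["t1"] == pytest.approx(4.0, rel=0.05)
        assert coefs["t3"] == pytest.approx(-2.5, rel=0.05)

    def test_alpha_one_keeps_everything(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        y = rng.normal(size=50)
        model = am.stepwise_ols(X, y, alpha=1.0)
        assert model.retained_ == list("abcd")

    def test_exact_single_term(self):
        x = np.linspace(1, 2, 40)
        X = pd.DataFrame({"x1": x})
        model = am.stepwise_ols(X, 3.0 * x)
        assert model.coef_[0] == pytest.approx(3.0)
        assert model.r2_ == pytest.approx(1.0)

    def test_pure_noise_degenerates(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": rng.normal(size=100)})
        y = rng.normal(size=100)
        with pytest.raises(DegenerateModelError):
            am.stepwise_ols(X, y, alpha=1e-6)

    def test_needs_more_rows_than_columns(self):
        X = pd.DataFrame(np.eye(5))
        with pytest.raises(DomainError):
            am.stepwise_ols(X, np.ones(5))

    def test_sklearn_params_round_trip(self):
        est = am.StepwiseOLS(alpha=0.01)
        assert est.get_params()["alpha"] == 0.01
        est.set_params(alpha=0.1)
        assert est.alpha == 0.1


class TestDiagnostics:
    def _fitted(self, seed=4, n=200):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({"a": rng.uniform(1, 2, n), "b": rng.uniform(1, 2, n)})
        y = 5.0 * X["a"] + 2.0 * X["b"] + 0.05 * rng.normal(size=n)
        return X, y, am.stepwise_ols(X, y)

    def test_clean_fit_has_no_outliers(self):
        X, y, model = self._fitted()
        assert am.flag_outliers(model, X, y) == []

    def test_injected_outlier_is_flagged(self):
        X, y, model = self._fitted()
        y2 = y.copy()
        y2.iloc[17] *= 10.0
        model2 = am.stepwise_ols(X, y2)
        assert am.flag_outliers(model2, X, y2) == [17]

    def test_infinite_threshold_flags_nothing(self):
        X, y, model = self._fitted()
        assert am.flag_outliers(model, X, y, threshold=np.inf) == []

    def test_mean_pct_error_arithmetic(self):
        assert am.mean_pct_error([100.0, 200.0], [110.0, 180.0]) == pytest.approx(10.0)
        assert am.mean_pct_error([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_excluding_worst_row_reduces_error(self):
        y = np.array([100.0, 100.0, 100.0])
        yhat = np.array([101.0, 99.0, 250.0])
        assert am.mean_pct_error(y, yhat, exclude=[2]) < am.mean_pct_error(y, yhat)

    def test_baseline_predicts_training_mean(self):
        mdl = am.baseline_mean_model([10.0, 20.0, 30.0])
        np.testing.assert_allclose(mdl.predict(np.empty((4, 0))), 20.0)
        single = am.baseline_mean_model([7.0])
        assert single.predict(np.empty((1, 0)))[0] == 7.0


class TestFitResponse:
    def test_metrics_invariant_under_row_permutation(self, noisy_study):
        cohort, _, _, summaries = noisy_study
        m1, *_ = am.fit_response(summaries, cohort, response="K_df")
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(len(summaries)))
        m2, *_ = am.fit_response([summaries[i] for i in perm], cohort,
                                 response="K_df")
        assert m2.r2 == pytest.approx(m1.r2, abs=1e-8)
        assert m2.n_components_cv == m1.n_components_cv
        assert m2.mean_pct_error == pytest.approx(m1.mean_pct_error, abs=1e-8)
        assert set(m2.coefficients) == set(m1.coefficients)

    def test_predicted_r2_never_exceeds_fit_r2(self, noisy_study):
        cohort, _, _, summaries = noisy_study
        for resp in ("K_df", "K_pf", "E"):
            m, *_ = am.fit_response(summaries, cohort, response=resp)
            assert m.pls_predicted_r2 <= m.pls_r2 + 1e-9

    def test_predict_consistent_with_training_fit(self, noisy_study):
        cohort, _, _, summaries = noisy_study
        model, X, y, _ = am.fit_response(summaries, cohort, response="K_pf")
        preds = model.predict_rows(X)
        s0 = next(s for s in summaries if np.isfinite(s.K_pf))
        subj = {c.subject_id: c for c in cohort}[s0.subject_id]
        p0 = am.predict(model, subj.weight, subj.height, s0.speed,
                        {"df": s0.Gamma_df, "dl": s0.Gamma_dl_signed,
                         "pf": s0.Gamma_pf})
        assert p0 == pytest.approx(preds[0], rel=1e-9)

    def test_predict_missing_excursion_raises(self, noisy_study):
        cohort, _, _, summaries = noisy_study
        model, *_ = am.fit_response(summaries, cohort, response="K_pf")
        with pytest.raises(DomainError):
            am.predict(model, 70.0, 1.7, 1.5, {})

    def test_model_json_round_trip(self, noisy_study):
        cohort, _, _, summaries = noisy_study
        model, *_ = am.fit_response(summaries, cohort, response="E")
        clone = am.FittedModel.from_dict(model.to_dict())
        gam = {"df": 0.2, "dl": 0.03, "pf": 0.48}
        assert clone.predict_point(70, 1.7, 1.5, gam) == pytest.approx(
            model.predict_point(70, 1.7, 1.5, gam)
        )
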