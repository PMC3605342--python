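"""Froude-optimal speed, preferred-trial selection, and model reduction."""

import numpy as np
import pytest

import anklemech as am
from anklemech.models import FittedModel, Term
from anklemech.types import DomainError, SubjectProfile

from test_models import make_summary


class TestOptimalSpeed:
    def test_hand_value(self):
        # sqrt(0.25 * 9.81 * 0.53 * 1.71)
        assert am.optimal_speed(1.71) == pytest.approx(1.491, abs=1e-3)

    def test_zero_froude(self):
        assert am.optimal_speed(1.71, froude_opt=0.0) == 0.0

    def test_monotone_in_height(self):
        assert am.optimal_speed(1.87) > am.optimal_speed(1.43)

    def test_nonpositive_height(self):
        with pytest.raises(DomainError):
            am.optimal_speed(0.0)


class TestNearestPreferredTrials:
    def _cohort(self):
        # H=1.7 -> optimal speed ~1.486 m/s
        return [SubjectProfile("S01", 70.0, 1.7, 1.486, 2.0)]

    def test_nearest_selected(self):
        sums = [make_summary(speed=v) for v in (1.0, 1.5, 2.0)]
        out = am.nearest_preferred_trials(sums, self._cohort())
        assert out["S01"].speed == 1.5

    def test_single_trial_subject(self):
        sums = [make_summary(speed=0.8)]
        assert am.nearest_preferred_trials(sums, self._cohort())["S01"].speed == 0.8

    def test_exact_tie_prefers_slower(self):
        # froude*g*leg*H = 2.25 -> v_opt exactly 1.5; speeds 1.0 / 2.0 tie
        cohort = [SubjectProfile("S01", 70.0, 1.0, 1.4, 1.9)]
        sums = [make_summary(speed=2.0), make_summary(speed=1.0)]
        out = am.nearest_preferred_trials(sums, cohort, froude_opt=2.25,
                                          leg_coeff=1.0, g=1.0)
        assert out["S01"].speed == 1.0


class TestMeanExcursions:
    def test_single_trial(self):
        me = am.mean_excursions_at_preferred([make_summary(g_df=0.2, g_dl=0.05,
                                                           g_pf=0.35)])
        assert (me.df, me.dl_signed, me.pf) == pytest.approx((0.2, 0.05, 0.35))

    def test_two_trial_mean(self):
        me = am.mean_excursions_at_preferred(
            [make_summary(g_df=0.2), make_summary(g_df=0.3)]
        )
        assert me.df == pytest.approx(0.25)

    def test_empty_selection(self):
        with pytest.raises(DomainError):
            am.mean_excursions_at_preferred([])

    def test_cohort_means_match_generator_distribution(self):
        """Preferred-speed excursion means land within 2 SE of the generator's
        excursion distribution means."""
        cohort, _, trials = am.simulate_study(seed=4)
        sums = am.summarize_trials(trials)
        me = am.mean_excursions_at_preferred(am.nearest_preferred_trials(sums, cohort))
        n = len(cohort)
        c = am.DEFAULT_COEFFS
        assert abs(me.df - c.gamma_df_mean) <= 2 * c.gamma_df_sd / np.sqrt(n) + 0.01
        assert abs(me.pf - c.gamma_pf_mean) <= 2 * c.gamma_pf_sd / np.sqrt(n) + 0.01


class TestReduceModel:
    def _model(self, terms, coeffs, response="K_df", intercept=False):
        basis = am.BasisSpec(response, tuple(terms), include_intercept=intercept)
        names = basis.term_names
        return FittedModel(
            basis=basis,
            coefficients=dict(zip(names, coeffs)),
            p_values={n: 0.0 for n in names},
            n_components_cv=1, pls_r2=100.0, pls_predicted_r2=100.0,
            r2=100.0, mean_pct_error=0.0,
        )

    def test_speed_term_becomes_h_to_three_halves(self):
        # c*W*H*V/G_df -> (c/G_mean)*kappa * W * H^1.5
        model = self._model([Term(w=1, h=1, v=1, phase="df", g_exp=-1)], [2.0])
        me = am.MeanExcursions(df=0.25, dl_signed=0.03, pf=0.48)
        sm = am.reduce_model(model, me)
        kappa = np.sqrt(0.25 * 9.81 * 0.53)
        assert set(sm.reduced) == {(1, 3)}  # W^1 * H^(3/2)
        assert sm.reduced[(1, 3)] == pytest.approx(2.0 * kappa / 0.25)
        assert sm.predict(70, 1.7) == pytest.approx(
            2.0 * kappa / 0.25 * 70 * 1.7**1.5
        )

    def test_intercept_only_model_reduces_to_constant(self):
        model = self._model([], [5.5], intercept=True)
        sm = am.reduce_model(model, am.MeanExcursions(0.2, 0.03, 0.48))
        assert sm.predict(60, 1.5) == pytest.approx(5.5)
        assert sm.predict(90, 1.9) == pytest.approx(5.5)

    def test_substitution_identity_at_operating_point(self, noisy_study):
        cohort, _, _, summaries = noisy_study
        me = am.mean_excursions_at_preferred(
            am.nearest_preferred_trials(summaries, cohort)
        )
        rng = np.random.default_rng(12)
        for resp in ("K_df", "K_dl", "K_pf", "E"):
            model, *_ = am.fit_response(summaries, cohort, response=resp)
            sm = am.reduce_model(model, me)
            for _ in range(100):
                W = rng.uniform(46, 94)
                H = rng.uniform(1.43, 1.87)
                v_opt = am.optimal_speed(H)
                src = model.predict_point(W, H, v_opt, me.as_gammas())
                assert abs(sm.predict(W, H) - src) < 1e-9 * max(1.0, abs(src))

    def test_dual_flexion_reduction_flagged_low_confidence(self):
        model = self._model([Term(w=1, h=1, phase="dl", g_exp=-1)], [1.0],
                            response="K_dl")
        sm = am.reduce_model(model, am.MeanExcursions(0.2, 0.03, 0.48))
        assert sm.low_confidence

    def test_zero_mean_excursion_rejected(self):
        model = self._model([Term(w=1, h=1, phase="df", g_exp=-1)], [1.0])
        with pytest.raises(DomainError):
            am.reduce_model(model, am.MeanExcursions(0.0, 0.03, 0.48))

    def test_stature_error_exceeds_general_form_error(self, noisy_study):
        """With excursions varying across subjects, the stature-based model
        must predict preferred-speed trials worse than the general form."""
        cohort, _, _, summaries = noisy_study
        subjects = {c.subject_id: c for c in cohort}
        pref = am.nearest_preferred_trials(summaries, cohort)
        me = am.mean_excursions_at_preferred(pref)
        for resp in ("K_df", "K_pf", "E"):
            model, *_ = am.fit_response(summaries, cohort, response=resp)
            sm = am.reduce_model(model, me)
            y, y_gen, y_stat = [], [], []
            for s in pref.values():
                subj = subjects[s.subject_id]
                y.append({"K_df": s.K_df, "K_pf": s.K_pf, "E": s.E_loop}[resp])
                gam = {"df": s.Gamma_df, "dl": s.Gamma_dl_signed, "pf": s.Gamma_pf}
                y_gen.append(model.predict_point(subj.weight, subj.height,
                                                 s.speed, gam))
                y_stat.append(sm.predict(subj.weight, subj.height))
            assert am.mean_pct_error(y, y_gen) < am.mean_pct_error(y, y_stat)
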