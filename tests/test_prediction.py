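"""Dynamic individual risk prediction: landmark posteriors, curve
properties, an independent scalar re-implementation oracle, the tower
identity, Monte-Carlo bands, and covariate-update re-prediction."""

import numpy as np
import pytest

import graftrisk as gr
from graftrisk.prediction import (
    posterior_class_at_landmark,
    predict_failure_probability,
    repredict_after_event_update,
    risk_curve_with_ci,
)
from graftrisk.survival import survival_given_class

from conftest import (
    fit_result_at,
    make_profile,
    true_params_fitted_convention,
)


@pytest.fixture(scope="module")
def tfit():
    """Fit object holding the generator's true parameters (no noise)."""
    cfg = gr.paper_like_preset()
    return fit_result_at(true_params_fitted_convention(cfg), 1)


def _class_history(cfg, g, times):
    """Measurements lying exactly on class g's mean trajectory."""
    b0, b1, b2 = np.asarray(cfg.beta, float)[g]
    return np.array([b0 + b1 * t + b2 * t * t for t in times])


class TestLandmarkPosterior:
    def test_single_class_returns_one(self):
        params = fit_result_at(
            gr.JointModelParams(
                n_classes=1,
                xi=np.zeros((0, 2)),
                beta=np.array([[5.0, 0.0, 0.0]]),
                B=np.eye(2) * 0.1,
                sigma=1.0,
                link=gr.LinkSpec("linear", None, np.array([0.0, 20.0]), (10.0, 500.0)),
                zeta=np.array([[0.05, 1.0]]),
                delta=np.zeros(5),
            ),
            1,
        )
        post = posterior_class_at_landmark(
            params, np.array([0.5]), np.array([100.0]), make_profile(), 1.0
        )
        np.testing.assert_allclose(post, [1.0])

    def test_history_on_class_mean_is_decisive(self, tfit):
        cfg = gr.paper_like_preset()
        times = np.array([0.1, 0.3, 0.6, 1.0])
        y3 = _class_history(cfg, 2, times)
        post = posterior_class_at_landmark(
            tfit, times, y3, make_profile(event_time=10.0), 1.0
        )
        assert post[2] > 0.99

    def test_normalization_over_random_subjects(self, tfit):
        rng = np.random.default_rng(8)
        for _ in range(100):
            times = np.sort(rng.uniform(0.05, 1.0, 4))
            y = rng.uniform(80, 300, 4)
            post = posterior_class_at_landmark(
                tfit, times, y, make_profile(event_time=9.0), 1.0
            )
            assert abs(post.sum() - 1.0) <= 1e-12

    def test_no_history_falls_back_with_warning(self, tfit):
        with pytest.warns(UserWarning, match="no measurements"):
            post = posterior_class_at_landmark(
                tfit, np.array([2.0]), np.array([150.0]), make_profile(), 1.0
            )
        assert abs(post.sum() - 1.0) <= 1e-12


class TestPointPrediction:
    def _subject(self, cfg):
        times = np.array([0.1, 0.3, 0.6, 1.0])
        return times, _class_history(cfg, 1, times), make_profile(event_time=10.0)

    def test_zero_at_landmark(self, tfit):
        cfg = gr.paper_like_preset()
        t, y, prof = self._subject(cfg)
        grid = np.linspace(1.0, 10.0, 25)
        P = predict_failure_probability(tfit, prof, t, y, 1.0, grid)
        assert P[0] == 0.0

    def test_monotone_and_bounded(self, tfit):
        cfg = gr.paper_like_preset()
        t, y, prof = self._subject(cfg)
        grid = np.linspace(1.0, 10.0, 25)
        P = predict_failure_probability(tfit, prof, t, y, 1.0, grid)
        assert np.all(np.diff(P) >= -1e-12)
        assert np.all((P >= 0) & (P <= 1))

    def test_matches_independent_scalar_reimplementation(self, tfit):
        """Re-derive P(s,t) with plain scalar arithmetic."""
        cfg = gr.paper_like_preset()
        t, y, prof = self._subject(cfg)
        s, grid = 1.0, np.linspace(1.0, 10.0, 12)
        P = predict_failure_probability(tfit, prof, t, y, s, grid)
        post = posterior_class_at_landmark(tfit, t, y, prof, s)
        x = prof.hazard_covariates()
        p = tfit.params
        expected = []
        for tt in grid:
            val = 0.0
            for g in range(3):
                Ss = float(survival_given_class(s, p.zeta[g], p.delta, x))
                St = float(survival_given_class(tt, p.zeta[g], p.delta, x))
                val += post[g] * (1.0 - St / Ss)
            expected.append(val)
        np.testing.assert_allclose(P, expected, atol=1e-10)

    def test_degenerate_posterior_collapses_to_class_curve(self, tfit):
        cfg = gr.paper_like_preset()
        times = np.array([0.1, 0.3, 0.6, 1.0])
        y3 = _class_history(cfg, 2, times)
        prof = make_profile(event_time=10.0)
        grid = np.linspace(1.0, 8.0, 15)
        P = predict_failure_probability(tfit, prof, times, y3, 1.0, grid)
        x = prof.hazard_covariates()
        p = tfit.params
        S1 = survival_given_class(1.0, p.zeta[2], p.delta, x)
        cond = 1.0 - survival_given_class(grid, p.zeta[2], p.delta, x) / S1
        np.testing.assert_allclose(P, cond, atol=1e-2)

    def test_tower_identity(self, tfit):
        """P(s,t) = P(s,s') + (1-P(s,s')) P(s',t) when no new measurements
        enter between the landmarks."""
        cfg = gr.paper_like_preset()
        t, y, prof = self._subject(cfg)
        s, s2, tend = 1.6, 3.0, 10.0
        P_s_t = predict_failure_probability(tfit, prof, t, y, s, np.array([tend]))[0]
        P_s_s2 = predict_failure_probability(tfit, prof, t, y, s, np.array([s2]))[0]
        P_s2_t = predict_failure_probability(tfit, prof, t, y, s2, np.array([tend]))[0]
        assert P_s_t == pytest.approx(P_s_s2 + (1 - P_s_s2) * P_s2_t, abs=1e-10)


class TestRiskCurveCI:
    def test_zero_vcov_band_collapses(self, tfit):
        cfg = gr.paper_like_preset()
        times = np.array([0.1, 0.5, 1.0])
        y = _class_history(cfg, 1, times)
        prof = make_profile(event_time=10.0)
        grid = np.linspace(1.0, 10.0, 20)
        curve = risk_curve_with_ci(tfit, prof, times, y, 1.0, grid, n_draws=50, seed=3)
        np.testing.assert_allclose(curve.lower95, curve.point, atol=1e-12)
        np.testing.assert_allclose(curve.upper95, curve.point, atol=1e-12)
        np.testing.assert_allclose(curve.median, curve.point, atol=1e-12)

    def test_deterministic_given_seed(self, paper_fit, paper_cohort):
        _, cohort, _ = paper_cohort
        subj = cohort.subjects[5]
        t, y = cohort.measurements_for(subj.subject_id)
        grid = np.linspace(1.0, 10.0, 20)
        c1 = risk_curve_with_ci(paper_fit, subj, t, y, 1.0, grid, n_draws=80, seed=11)
        c2 = risk_curve_with_ci(paper_fit, subj, t, y, 1.0, grid, n_draws=80, seed=11)
        np.testing.assert_array_equal(c1.median, c2.median)
        np.testing.assert_array_equal(c1.lower95, c2.lower95)
        np.testing.assert_array_equal(c1.upper95, c2.upper95)

    def test_band_brackets_median_and_is_monotone(self, paper_fit, paper_cohort):
        _, cohort, _ = paper_cohort
        subj = cohort.subjects[0]
        t, y = cohort.measurements_for(subj.subject_id)
        grid = np.linspace(1.0, 10.0, 20)
        c = risk_curve_with_ci(paper_fit, subj, t, y, 1.0, grid, n_draws=80, seed=1)
        assert np.all(c.lower95 <= c.median + 1e-12)
        assert np.all(c.median <= c.upper95 + 1e-12)
        assert np.all(np.diff(c.median) >= -1e-10)

    def test_missing_vcov_flagged(self, tfit):
        import dataclasses

        nofit = dataclasses.replace(tfit, vcov=None)
        cfg = gr.paper_like_preset()
        times = np.array([0.1, 0.5, 1.0])
        y = _class_history(cfg, 0, times)
        with pytest.warns(UserWarning, match="variance"):
            c = risk_curve_with_ci(
                nofit, make_profile(), times, y, 1.0, np.linspace(1, 10, 10)
            )
        assert c.n_draws == 0


class TestReprediction:
    def test_identity_update(self, tfit):
        cfg = gr.paper_like_preset()
        times = np.array([0.1, 0.5, 1.0])
        y = _class_history(cfg, 1, times)
        prof = make_profile(event_time=10.0)
        grid = np.linspace(1.0, 10.0, 20)
        base = risk_curve_with_ci(tfit, prof, times, y, 1.0, grid, n_draws=40, seed=2)
        re = repredict_after_event_update(
            tfit, prof, times, y, 1.0, {}, grid=grid, n_draws=40, seed=2
        )
        np.testing.assert_allclose(re.median, base.median, atol=1e-12)

    def test_dndsa_and_rejection_raise_risk(self, tfit):
        """With exp(delta_dndsa + delta_ar + delta_interaction) > 1 (the
        fitted signs), switching both on strictly raises the curve."""
        cfg = gr.paper_like_preset()
        assert np.exp(cfg.delta[2] + cfg.delta[3] + cfg.delta[4]) > 1
        times = np.array([0.1, 0.5, 1.0, 1.4])
        y = _class_history(cfg, 1, times)
        prof = make_profile(event_time=10.0)
        grid = np.linspace(2.0, 10.0, 20)
        base = risk_curve_with_ci(tfit, prof, times, y, 2.0, grid, n_draws=20, seed=4)
        re = repredict_after_event_update(
            tfit, prof, times, y, 2.0,
            {"dndsa": 1, "dndsa_time": 2.0, "acute_rejection": 1, "ar_time": 1.8},
            grid=grid, n_draws=20, seed=4,
        )
        assert np.all(re.point[1:] > base.point[1:])
        # and the updated curve still satisfies the curve invariants
        assert np.all(np.diff(re.median) >= -1e-10)
        assert np.all((re.median >= 0) & (re.median <= 1))

    def test_landmark_moves_to_onset(self, tfit):
        cfg = gr.paper_like_preset()
        times = np.array([0.1, 0.5, 1.0])
        y = _class_history(cfg, 1, times)
        prof = make_profile(event_time=10.0)
        re = repredict_after_event_update(
            tfit, prof, times, y, 1.0,
            {"dndsa": 1, "dndsa_time": 3.5}, n_draws=10, seed=0,
        )
        assert re.landmark == 3.5
        assert np.all(re.grid >= 3.5)
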