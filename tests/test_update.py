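import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from akiscore.errors import (DesignError, InvalidInputError, SeparationError)
from akiscore.score import DEFAULT_WEIGHTS, cohort_scores
from akiscore.simulate import GeneratorConfig, TrueOutcomeParams, generate_cohort
from akiscore.update import (assign_score_points, candidate_scan,
                             delta_aic_significant, fit_logistic,
                             recalibrate_extend, vif)


def loglik(design, y, beta):
    X = np.column_stack([np.ones(len(y)), np.asarray(design)])
    lp = X @ beta
    return float(np.sum(y * lp - np.logaddexp(0.0, lp)))


class TestFitLogistic:
    def test_intercept_only_matches_mean(self):
        y = np.array([0, 0, 0, 1, 1])
        fit = fit_logistic(np.empty((5, 0)), y)
        assert expit(fit.coefficients[0]) == pytest.approx(y.mean(), abs=1e-8)

    def test_matches_grid_search_oracle(self, rng):
        # independent two-stage grid maximisation of the likelihood
        n = 20
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(0.3 + 0.9 * x)).astype(int)
        fit = fit_logistic(x.reshape(-1, 1), y)
        centre = np.array([0.0, 0.0])
        width = 8.0
        for _ in range(12):
            grid_a = np.linspace(centre[0] - width, centre[0] + width, 41)
            grid_b = np.linspace(centre[1] - width, centre[1] + width, 41)
            best, best_ll = None, -np.inf
            for a in grid_a:
                for b in grid_b:
                    ll = loglik(x, y, np.array([a, b]))
                    if ll > best_ll:
                        best, best_ll = np.array([a, b]), ll
            centre, width = best, width / 8
        assert fit.coefficients == pytest.approx(centre, abs=1e-4)

    def test_all_one_outcome_degenerate(self):
        with pytest.raises(SeparationError):
            fit_logistic(np.arange(6).reshape(-1, 1), np.ones(6))

    def test_perfect_separation(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0]).reshape(-1, 1)
        y = (x.ravel() > 0).astype(int)
        with pytest.raises(SeparationError):
            fit_logistic(x, y)

    def test_rank_deficient_design(self):
        x = np.ones((10, 1))  # duplicates the intercept
        y = np.array([0, 1] * 5)
        with pytest.raises(DesignError):
            fit_logistic(x, y)

    def test_aic_identity(self, rng):
        x = rng.normal(size=80)
        y = (rng.random(80) < expit(x)).astype(int)
        fit = fit_logistic(x.reshape(-1, 1), y)
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)

    def test_gradient_vanishes_at_solution(self, rng):
        x = rng.normal(size=200)
        y = (rng.random(200) < expit(0.5 * x - 0.5)).astype(int)
        fit = fit_logistic(x.reshape(-1, 1), y)
        X = np.column_stack([np.ones(200), x])
        grad = X.T @ (y - expit(X @ fit.coefficients))
        assert np.linalg.norm(grad) < 1e-6

    def test_deterministic(self, rng):
        x = rng.normal(size=50)
        y = (rng.random(50) < 0.4).astype(int)
        f1 = fit_logistic(x.reshape(-1, 1), y)
        f2 = fit_logistic(x.reshape(-1, 1), y)
        assert np.array_equal(f1.coefficients, f2.coefficients)

    def test_nested_model_aic_bound(self, rng):
        # AIC(larger) <= AIC(smaller) + 2*(added params): likelihood never drops
        x = rng.normal(size=(120, 2))
        y = (rng.random(120) < expit(0.5 * x[:, 0])).astype(int)
        small = fit_logistic(x[:, :1], y)
        large = fit_logistic(x, y)
        assert large.aic <= small.aic + 2.0 + 1e-9


class TestRecalibrateExtend:
    def test_pure_recalibration_reduction(self, medium_cohort):
        cohort, _ = medium_cohort
        y = cohort.outcomes()
        score = cohort_scores(cohort, DEFAULT_WEIGHTS)
        fit = recalibrate_extend(score, None, y)
        assert fit.k == 2
        assert fit.names == ("intercept", "score")

    def test_recovers_designed_odds_ratios(self):
        cohort, _ = generate_cohort(GeneratorConfig(n=20_000), 42)
        y = cohort.outcomes()
        score = cohort_scores(cohort, DEFAULT_WEIGHTS)
        no_mg = cohort.column("no_mg").astype(float)
        fit = recalibrate_extend(score, no_mg.reshape(-1, 1), y)
        lo, hi = fit.wald_ci(1)
        assert lo <= math.log(1.29) <= hi
        lo, hi = fit.wald_ci(2)
        assert lo <= math.log(3.91) <= hi

    def test_collinear_extra_rejected(self, medium_cohort):
        cohort, _ = medium_cohort
        y = cohort.outcomes()
        score = cohort_scores(cohort, DEFAULT_WEIGHTS)
        with pytest.raises(DesignError):
            recalibrate_extend(score, score.reshape(-1, 1), y)


class TestCandidateScan:
    def test_empty_candidates_base_only(self, medium_cohort):
        cohort, _ = medium_cohort
        score = cohort_scores(cohort, DEFAULT_WEIGHTS)
        rows = candidate_scan(cohort, score, [])
        assert len(rows) == 1 and rows[0].candidate == "None"
        assert rows[0].delta_aic == 0.0 and not rows[0].significant

    def test_true_predictor_wins(self, medium_cohort):
        cohort, _ = medium_cohort
        score = cohort_scores(cohort, DEFAULT_WEIGHTS)
        rows = candidate_scan(cohort, score, ["no_mg", "gem", "dtx", "sh"])
        fitted = [r for r in rows if r.fitted]
        assert fitted[0].candidate == "no_mg"  # sorted by AIC ascending
        assert fitted[0].significant

    def test_null_candidate_small_delta(self, rng):
        # a candidate independent of the outcome rarely moves AIC much
        cohort, _ = generate_cohort(GeneratorConfig(n=5000), 21)
        score = cohort_scores(cohort, DEFAULT_WEIGHTS)
        rows = candidate_scan(cohort, score, ["dtx"])  # no designed effect
        row = next(r for r in rows if r.candidate == "dtx")
        assert row.delta_aic <= 4.0
        assert not row.significant

    def test_zero_variance_flagged(self, medium_cohort, caplog):
        cohort, _ = medium_cohort
        score = cohort_scores(cohort, DEFAULT_WEIGHTS)
        rows = candidate_scan(cohort, score, ["egfri"])
        row = next(r for r in rows if r.candidate == "egfri")
        if not row.fitted:
            assert row.aic is None


class TestDeltaAic:
    def test_published_mg_row_significant(self):
        assert delta_aic_significant(1240.5, 1175.3)

    def test_published_s1_row_not_significant(self):
        assert not delta_aic_significant(1240.5, 1235.1)

    def test_equal_not_significant(self):
        assert not delta_aic_significant(100.0, 100.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidInputError):
            delta_aic_significant(float("nan"), 1.0)


class TestAssignScorePoints:
    def test_published_assignment(self):
        a = assign_score_points(3.91, 1.29)
        assert a.raw_ratio == pytest.approx(3.031, abs=5e-4)
        assert a.points == 3.0

    def test_identity_ratio(self):
        assert assign_score_points(1.29, 1.29).points == 1.0

    def test_hand_rounding(self):
        a = assign_score_points(2.0, 1.3)
        assert a.raw_ratio == pytest.approx(1.538, abs=5e-4)
        assert a.points == 1.5

    def test_tie_rounds_away_from_zero(self):
        assert assign_score_points(1.25, 1.0).points == 1.5

    def test_log_scale_alternative(self):
        a = assign_score_points(3.91, 1.29, log_scale=True)
        assert a.raw_ratio == pytest.approx(math.log(3.91) / math.log(1.29))
        assert a.points == 5.5

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidInputError):
            assign_score_points(-1.0, 1.3)

    @given(or_new=st.floats(0.05, 50.0), or_pp=st.floats(1.01, 3.0))
    @settings(max_examples=200)
    def test_grid_property(self, or_new, or_pp):
        pts = assign_score_points(or_new, or_pp).points
        assert (2 * pts) == int(2 * pts)

    @given(or_a=st.floats(0.1, 20.0), or_b=st.floats(0.1, 20.0))
    @settings(max_examples=100)
    def test_monotone_in_or_new(self, or_a, or_b):
        lo, hi = sorted((or_a, or_b))
        assert (assign_score_points(lo, 1.29).points
                <= assign_score_points(hi, 1.29).points)


class TestVif:
    def test_orthogonal_predictors(self):
        n = 64
        x = np.column_stack([np.tile([1.0, -1.0], n // 2),
                             np.repeat([1.0, -1.0], n // 2)])
        out = vif(x)
        assert all(v == pytest.approx(1.0) for v in out.values())

    def test_near_collinearity_flagged(self, rng):
        x1 = rng.normal(size=300)
        x2 = x1 + rng.normal(scale=1e-4, size=300)
        out = vif(np.column_stack([x1, x2]), names=("a", "b"))
        assert out["a"] > 3 and out["b"] > 3

    def test_exact_collinearity_infinite(self, rng):
        x1 = rng.normal(size=100)
        out = vif(np.column_stack([x1, 2 * x1]))
        assert math.isinf(out["x0"]) and math.isinf(out["x1"])

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.outliers_influence import \
            variance_inflation_factor
        x = rng.normal(size=(200, 3))
        x[:, 2] += 0.7 * x[:, 0]
        ours = vif(x)
        X = np.column_stack([np.ones(200), x])
        for j in range(3):
            expected = variance_inflation_factor(X, j + 1)
            assert ours[f"x{j}"] == pytest.approx(expected, rel=1e-6)

    def test_single_column_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            vif(rng.normal(size=(50, 1)))
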