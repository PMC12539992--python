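import math

import numpy as np
import pytest
from scipy.special import expit, logit

from akiscore.errors import InvalidInputError, SeparationError
from akiscore.performance import (BootstrapConfig, brier_score,
                                  c_statistic, calibration_in_the_large,
                                  calibration_slope, compute_metrics,
                                  cox_snell_r2, ici, nagelkerke_r2, oe_ratio,
                                  bootstrap_metrics, optimism_corrected_c)
from akiscore.score import ScoreModel, DEFAULT_WEIGHTS
from akiscore.simulate import GeneratorConfig, generate_cohort


def brute_force_c(p, y):
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=int)
    num = tot = 0.0
    for pe in p[y == 1]:
        for pn in p[y == 0]:
            tot += 1
            if pe > pn:
                num += 1
            elif pe == pn:
                num += 0.5
    return num / tot


class TestBrier:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 1, 0])
        assert brier_score(y.astype(float), y) == 0.0

    def test_all_half(self, rng):
        y = (rng.random(50) < 0.3).astype(int)
        assert brier_score(np.full(50, 0.5), y) == pytest.approx(0.25)

    def test_hand_arithmetic(self):
        assert brier_score([0.8, 0.3], [1, 0]) == pytest.approx(0.065)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            brier_score([], [])


class TestR2:
    def test_equal_logliks_zero(self):
        assert cox_snell_r2(-50.0, -50.0, 100) == 0.0

    def test_hand_arithmetic(self):
        cs = cox_snell_r2(-90.0, -100.0, 100)
        assert cs == pytest.approx(1 - math.exp(-0.2))
        nk = nagelkerke_r2(-90.0, -100.0, 100)
        assert nk == pytest.approx(cs / (1 - math.exp(-2.0)))

    def test_worse_than_null_negative(self):
        # a fixed external model may fit worse than the null
        assert cox_snell_r2(-105.0, -100.0, 100) < 0.0


class TestCalibrationInTheLarge:
    def test_self_consistency(self, rng):
        n = 20_000
        lp = rng.normal(-2.0, 1.0, size=n)
        y = (rng.random(n) < expit(lp)).astype(int)
        assert calibration_in_the_large(lp, y) == pytest.approx(0.0, abs=0.06)

    def test_shift_equivariance(self, rng):
        n = 20_000
        lp = rng.normal(-1.5, 0.8, size=n)
        y = (rng.random(n) < expit(lp)).astype(int)
        shifted = calibration_in_the_large(lp - 0.7, y)
        assert shifted == pytest.approx(0.7, abs=0.08)

    def test_degenerate_outcome(self):
        with pytest.raises(SeparationError):
            calibration_in_the_large(np.zeros(10), np.ones(10))


class TestCalibrationSlope:
    def test_self_consistency(self, rng):
        n = 20_000
        lp = rng.normal(-2.0, 1.2, size=n)
        y = (rng.random(n) < expit(lp)).astype(int)
        assert calibration_slope(lp, y) == pytest.approx(1.0, abs=0.07)

    def test_scale_equivariance(self, rng):
        n = 20_000
        lp = rng.normal(-1.0, 1.0, size=n)
        y = (rng.random(n) < expit(lp)).astype(int)
        assert calibration_slope(2.0 * lp, y) == pytest.approx(0.5, abs=0.05)

    def test_overconfident_below_one(self, rng):
        # overdispersed predictions => slope < 1 (the direction seen when an
        # externally derived score is too extreme for the cohort)
        n = 20_000
        lp = rng.normal(-2.0, 0.8, size=n)
        y = (rng.random(n) < expit(lp)).astype(int)
        assert calibration_slope(3.0 * lp + 1.0, y) < 1.0

    def test_constant_lp_rejected(self):
        with pytest.raises(InvalidInputError):
            calibration_slope(np.zeros(30), np.tile([0, 1], 15))


class TestOERatio:
    def test_aggregate_calibrated(self):
        y = np.array([1, 0, 0, 0])
        p = np.full(4, 0.25)
        assert oe_ratio(p, y) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        y = np.array([1] * 10 + [0] * 10)
        p = np.full(20, 1.0)
        assert oe_ratio(p, y) == pytest.approx(0.5)

    def test_overestimation_below_one(self, rng):
        n = 5000
        p = rng.uniform(0.1, 0.5, size=n)
        y = (rng.random(n) < 0.5 * p).astype(int)
        assert oe_ratio(p, y) < 1.0

    def test_zero_expected_rejected(self):
        with pytest.raises(InvalidInputError):
            oe_ratio(np.zeros(5), np.zeros(5))


class TestIci:
    def test_constant_at_event_rate(self, rng):
        n = 20_000
        y = (rng.random(n) < 0.3).astype(int)
        p = np.full(n, y.mean()) + rng.normal(0, 1e-6, n)  # lowess needs spread
        assert ici(p, y) == pytest.approx(0.0, abs=0.01)

    def test_consistency(self, rng):
        n = 20_000
        p = rng.uniform(0.02, 0.6, size=n)
        y = (rng.random(n) < p).astype(int)
        assert ici(p, y) < 0.02

    def test_constant_shift_oracle(self, rng):
        n = 20_000
        p = rng.uniform(0.1, 0.5, size=n)
        y = (rng.random(n) < p).astype(int)
        shifted = np.clip(p + 0.05, 0, 1)
        assert ici(shifted, y) == pytest.approx(0.05, abs=0.012)

    def test_small_n_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            ici(rng.random(10), np.tile([0, 1], 5))


class TestCStatistic:
    def test_perfect_separation(self):
        assert c_statistic([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_equal_half(self):
        assert c_statistic(np.full(10, 0.3), [1, 0] * 5) == 0.5

    def test_hand_enumeration(self):
        assert c_statistic([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_one_class_rejected(self):
        with pytest.raises(InvalidInputError):
            c_statistic([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 200)
        p = np.round(rng.random(n), 2)  # ties likely
        y = (rng.random(n) < 0.4).astype(int)
        if y.min() == y.max():
            return
        assert c_statistic(p, y) == pytest.approx(brute_force_c(p, y))

    def test_permutation_invariance(self, rng):
        p = rng.random(80)
        y = (rng.random(80) < 0.3).astype(int)
        y[0] = 1
        y[1] = 0
        perm = rng.permutation(80)
        assert c_statistic(p[perm], y[perm]) == pytest.approx(
            c_statistic(p, y))


class TestJointCalibrationSanity:
    def test_self_generated_data(self, rng):
        # model evaluated on data generated from itself: all calibration
        # metrics sit at their ideal values
        n = 20_000
        lp = rng.normal(-2.2, 1.0, size=n)
        y = (rng.random(n) < expit(lp)).astype(int)
        m = compute_metrics(lp, y)
        assert m["r2_cox_snell"] > 0
        assert m["calibration_slope"] == pytest.approx(1.0, abs=0.07)
        assert m["calibration_in_the_large"] == pytest.approx(0.0, abs=0.06)
        assert m["oe_ratio"] == pytest.approx(1.0, abs=0.05)
        assert m["ici"] < 0.02


@pytest.fixture(scope="module")
def cohort():
    cohort, _ = generate_cohort(GeneratorConfig(n=500), seed=3)
    return cohort


@pytest.fixture(scope="module")
def model():
    return ScoreModel(weights=DEFAULT_WEIGHTS, intercept=-3.178, slope=0.399)


class TestBootstrapMetrics:
    def test_boot_mean_near_point_for_brier(self, cohort, model):
        rep = bootstrap_metrics(cohort, model,
                                BootstrapConfig(B=400, seed=1),
                                metrics=("brier",))
        s = rep["brier"]
        assert s.ci_low <= s.point <= s.ci_high
        # bootstrap mean within a few MC standard errors of the point value
        assert abs(s.boot_mean - s.point) < 0.01

    def test_seed_stability(self, cohort, model):
        kwargs = dict(metrics=("brier", "c_statistic"))
        r1 = bootstrap_metrics(cohort, model, BootstrapConfig(B=2000, seed=1),
                               **kwargs)
        r2 = bootstrap_metrics(cohort, model, BootstrapConfig(B=2000, seed=2),
                               **kwargs)
        for m in kwargs["metrics"]:
            w = r1[m].ci_high - r1[m].ci_low
            assert abs(r1[m].ci_low - r2[m].ci_low) < 0.1 * w
            assert abs(r1[m].ci_high - r2[m].ci_high) < 0.1 * w

    def test_deterministic_given_seed(self, cohort, model):
        cfg = BootstrapConfig(B=100, seed=9)
        r1 = bootstrap_metrics(cohort, model, cfg, metrics=("c_statistic",))
        r2 = bootstrap_metrics(cohort, model, cfg, metrics=("c_statistic",))
        assert r1["c_statistic"] == r2["c_statistic"]

    def test_skip_warning_on_tiny_cohort(self, model):
        cohort, _ = generate_cohort(GeneratorConfig(n=8), seed=14)
        y = cohort.outcomes()
        if y.sum() == 0:  # make sure at least one event exists
            pytest.skip("no event drawn in tiny cohort")
        with pytest.warns(RuntimeWarning, match="skipped"):
            bootstrap_metrics(cohort, model, BootstrapConfig(B=300, seed=0),
                              metrics=("brier",))

    def test_normal_ci_flag(self, cohort, model):
        rep = bootstrap_metrics(cohort, model,
                                BootstrapConfig(B=200, seed=4, normal_ci=True),
                                metrics=("brier",))
        s = rep["brier"]
        assert s.ci_low < s.point < s.ci_high


class TestOptimism:
    def test_data_ignoring_builder_zero_optimism(self, small_cohort):
        cohort, _ = small_cohort

        def builder(_c):
            model = ScoreModel(weights=DEFAULT_WEIGHTS, intercept=-3.178,
                               slope=0.399)

            def predict(cc):
                from akiscore.score import cohort_scores, predict_probability
                return predict_probability(model,
                                           cohort_scores(cc, model.weights))
            return predict

        # with a fixed model C_test is constant but C_boot still varies with
        # the resample, so the mean optimism is zero only in expectation
        res = optimism_corrected_c(cohort, builder,
                                   BootstrapConfig(B=400, seed=2))
        assert res.mean_optimism == pytest.approx(0.0, abs=0.01)
        assert res.corrected_c == pytest.approx(res.apparent_c, abs=0.01)

    def test_refitting_builder_positive_optimism(self, medium_cohort):
        from akiscore.score import cohort_scores
        from akiscore.update import recalibrate_extend
        cohort, _ = medium_cohort

        def builder(c):
            y = c.outcomes()
            s = cohort_scores(c, DEFAULT_WEIGHTS)
            x = c.column("no_mg").astype(float)
            fit = recalibrate_extend(s, x.reshape(-1, 1), y)

            def predict(cc):
                sb = cohort_scores(cc, DEFAULT_WEIGHTS)
                xb = cc.column("no_mg").astype(float)
                return fit.predict(np.column_stack([sb, xb]))
            return predict

        res = optimism_corrected_c(cohort, builder,
                                   BootstrapConfig(B=100, seed=5))
        assert res.corrected_c <= res.apparent_c + 1e-9
        assert 0.0 <= res.corrected_c <= 1.0
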