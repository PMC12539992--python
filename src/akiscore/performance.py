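"""Validation metric battery: overall fit, calibration, discrimination,
bootstrap confidence intervals, and the optimism-corrected C-statistic.

The evaluated model is held fixed (its coefficients are not refit on the
evaluation data), which is what allows a negative Cox-Snell R-squared when an
externally specified model fits worse than the null.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cohort import Cohort, take_unchecked
from .errors import InvalidInputError, SeparationError
from .score import ScoreModel, cohort_scores
from .update import fit_intercept_only, fit_logistic

__all__ = [
    "MetricSummary",
    "PerformanceReport",
    "BootstrapConfig",
    "OptimismResult",
    "brier_score",
    "cox_snell_r2",
    "nagelkerke_r2",
    "calibration_in_the_large",
    "calibration_slope",
    "oe_ratio",
    "ici",
    "c_statistic",
    "compute_metrics",
    "bootstrap_metrics",
    "optimism_corrected_c",
]

logger = logging.getLogger(__name__)

_CLIP = 1e-12

METRIC_NAMES = ("r2_cox_snell", "r2_nagelkerke", "brier",
                "calibration_in_the_large", "calibration_slope", "oe_ratio",
                "ici", "c_statistic")


@dataclass(frozen=True)
class MetricSummary:
    point: float
    boot_mean: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


@dataclass(frozen=True)
class PerformanceReport:
    metrics: dict[str, MetricSummary]
    n: int
    B: int
    seed: Optional[int]
    skipped_replicates: int = 0

    def __getitem__(self, name: str) -> MetricSummary:
        return self.metrics[name]


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings; the published analyses used B=10,000."""

    B: int = 10_000
    seed: int = 0
    ci: float = 0.95
    normal_ci: bool = False  # percentile interval by default

    def __post_init__(self) -> None:
        if self.B < 1:
            raise InvalidInputError("B must be >= 1")
        if not 0.0 < self.ci < 1.0:
            raise InvalidInputError("ci level must lie in (0, 1)")


@dataclass(frozen=True)
class OptimismResult:
    apparent_c: float
    mean_optimism: float
    corrected_c: float
    B: int
    seed: int
    skipped_replicates: int = 0


def _check_probs(p: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.size != y.size or p.size == 0:
        raise InvalidInputError("p and y must be non-empty and equal length")
    if np.any((p < 0) | (p > 1)):
        raise InvalidInputError("probabilities must lie in [0, 1]")
    return p, y


def brier_score(p: Sequence[float], y: Sequence[int]) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p, y = _check_probs(np.asarray(p), np.asarray(y))
    return float(np.mean((p - y) ** 2))


def cox_snell_r2(loglik_model: float, loglik_null: float, n: int) -> float:
    """May be negative when a fixed external model fits worse than null."""
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    return 1.0 - math.exp(-2.0 * (loglik_model - loglik_null) / n)


def nagelkerke_r2(loglik_model: float, loglik_null: float, n: int) -> float:
    cs = cox_snell_r2(loglik_model, loglik_null, n)
    return cs / (1.0 - math.exp(2.0 * loglik_null / n))


def _bernoulli_loglik(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, _CLIP, 1.0 - _CLIP)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def calibration_in_the_large(lp: Sequence[float], y: Sequence[int]) -> float:
    """Intercept of a logistic fit of ``y`` with ``lp`` as a fixed offset."""
    lp = np.asarray(lp, dtype=float)
    y = np.asarray(y, dtype=float)
    fit = fit_intercept_only(y, offset=lp)
    return float(fit.coefficients[0])


def calibration_slope(lp: Sequence[float], y: Sequence[int]) -> float:
    """Slope of a logistic fit of ``y`` on ``lp`` with a free intercept;
    below 1 indicates overconfident (overdispersed) predictions."""
    lp = np.asarray(lp, dtype=float)
    if np.ptp(lp) == 0:
        raise InvalidInputError("linear predictor is constant")
    fit = fit_logistic(lp.reshape(-1, 1), y)
    return float(fit.coefficients[1])


def oe_ratio(p: Sequence[float], y: Sequence[int]) -> float:
    """Observed events over expected events; below 1 means overestimation."""
    p, y = _check_probs(np.asarray(p), np.asarray(y))
    expected = float(np.sum(p))
    if expected <= 0:
        raise InvalidInputError("expected event count is zero")
    return float(np.sum(y)) / expected


def ici(p: Sequence[float], y: Sequence[int], span: float = 0.75) -> float:
    """Integrated calibration index: mean absolute gap between predicted
    probability and a locally weighted (tricube, degree-1) smooth of the
    outcome on the prediction."""
    p, y = _check_probs(np.asarray(p), np.asarray(y))
    if p.size < 20:
        raise InvalidInputError("ici needs at least 20 observations")
    delta = 0.005 * float(np.ptp(p)) if p.size > 5000 else 0.0
    smooth = lowess(y, p, frac=span, it=0, delta=delta, return_sorted=False)
    return float(np.mean(np.abs(smooth - p)))


def c_statistic(p: Sequence[float], y: Sequence[int]) -> float:
    """Concordance: fraction of (event, non-event) pairs ranked correctly,
    ties counted one half."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=int)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise InvalidInputError("both outcome classes must be present")
    ranks = rankdata(p)  # midranks handle ties
    u = float(np.sum(ranks[y == 1])) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def compute_metrics(lp: Sequence[float], y: Sequence[int],
                    metrics: Sequence[str] = METRIC_NAMES) -> dict[str, float]:
    """Evaluate the requested metrics for a fixed linear predictor."""
    lp = np.asarray(lp, dtype=float)
    y = np.asarray(y, dtype=float)
    p = expit(lp)
    out: dict[str, float] = {}
    if "r2_cox_snell" in metrics or "r2_nagelkerke" in metrics:
        ll_model = _bernoulli_loglik(p, y)
        ll_null = _bernoulli_loglik(np.full_like(p, y.mean()), y)
        if "r2_cox_snell" in metrics:
            out["r2_cox_snell"] = cox_snell_r2(ll_model, ll_null, y.size)
        if "r2_nagelkerke" in metrics:
            out["r2_nagelkerke"] = nagelkerke_r2(ll_model, ll_null, y.size)
    if "brier" in metrics:
        out["brier"] = brier_score(p, y)
    if "calibration_in_the_large" in metrics:
        out["calibration_in_the_large"] = calibration_in_the_large(lp, y)
    if "calibration_slope" in metrics:
        out["calibration_slope"] = calibration_slope(lp, y)
    if "oe_ratio" in metrics:
        out["oe_ratio"] = oe_ratio(p, y)
    if "ici" in metrics:
        out["ici"] = ici(p, y)
    if "c_statistic" in metrics:
        out["c_statistic"] = c_statistic(p, y)
    return out


def bootstrap_metrics(cohort: Cohort, model: ScoreModel,
                      config: BootstrapConfig,
                      metrics: Sequence[str] = METRIC_NAMES,
                      ) -> PerformanceReport:
    """Point estimates plus bootstrap mean and percentile CI per metric.

    Patients are resampled with replacement; the model stays fixed (no
    refitting).  Replicates whose resample has a single outcome class, or
    where a metric is degenerate, are skipped and counted; a warning is
    emitted when more than 1% are skipped.
    """
    y = cohort.outcomes().astype(float)
    scores = cohort_scores(cohort, model.weights)
    lp = model.intercept + model.slope * scores
    points = compute_metrics(lp, y, metrics)

    rng = np.random.default_rng(config.seed)
    n = y.size
    samples: dict[str, list[float]] = {m: [] for m in metrics}
    skipped = 0
    for _ in range(config.B):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max():
            skipped += 1
            continue
        try:
            vals = compute_metrics(lp[idx], yb, metrics)
        except (InvalidInputError, SeparationError):
            skipped += 1
            continue
        for m in metrics:
            samples[m].append(vals[m])
    if skipped > 0.01 * config.B:
        warnings.warn(f"{skipped}/{config.B} bootstrap replicates skipped",
                      RuntimeWarning, stacklevel=2)

    alpha = 1.0 - config.ci
    summary: dict[str, MetricSummary] = {}
    for m in metrics:
        vals = np.asarray(samples[m])
        if vals.size == 0:
            summary[m] = MetricSummary(points[m])
            continue
        if config.normal_ci:
            from scipy.stats import norm
            z = norm.ppf(1.0 - alpha / 2.0)
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            lo, hi = points[m] - z * sd, points[m] + z * sd
        else:
            lo, hi = np.quantile(vals, [alpha / 2.0, 1.0 - alpha / 2.0])
        summary[m] = MetricSummary(points[m], float(vals.mean()),
                                   float(lo), float(hi))
    return PerformanceReport(metrics=summary, n=n, B=config.B,
                             seed=config.seed, skipped_replicates=skipped)


def optimism_corrected_c(cohort: Cohort,
                         model_builder: Callable[[Cohort], Callable[[Cohort], np.ndarray]],
                         config: BootstrapConfig) -> OptimismResult:
    """Bootstrap optimism correction of the C-statistic.

    ``model_builder`` reruns the full model-building process on a cohort and
    returns a predictor mapping any cohort to per-patient probabilities.
    Each replicate builds on a bootstrap sample, evaluates concordance on
    that sample and on the original cohort, and their mean difference is
    subtracted from the apparent concordance.
    """
    y = cohort.outcomes().astype(float)
    predict_full = model_builder(cohort)
    apparent = c_statistic(predict_full(cohort), y)

    rng = np.random.default_rng(config.seed)
    n = len(cohort)
    optimisms: list[float] = []
    skipped = 0
    for _ in range(config.B):
        idx = rng.integers(0, n, size=n)
        boot = take_unchecked(cohort, idx)
        yb = y[idx]
        if yb.min() == yb.max():
            skipped += 1
            continue
        try:
            predict_boot = model_builder(boot)
            c_boot = c_statistic(predict_boot(boot), yb)
            c_test = c_statistic(predict_boot(cohort), y)
        except (InvalidInputError, SeparationError) as exc:
            logger.debug("optimism replicate skipped: %s", exc)
            skipped += 1
            continue
        optimisms.append(c_boot - c_test)
    mean_opt = float(np.mean(optimisms)) if optimisms else 0.0
    return OptimismResult(apparent_c=apparent, mean_optimism=mean_opt,
                          corrected_c=apparent - mean_opt, B=config.B,
                          seed=config.seed, skipped_replicates=skipped)
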