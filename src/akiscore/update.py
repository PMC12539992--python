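"""Logistic fitting and the recalibration-and-extension updating procedure.

The fitter is a Newton-Raphson maximiser with step halving, so the
log-likelihood is non-decreasing across iterations.  Candidate predictors are
scanned one at a time on top of the base score; an AIC drop greater than 10
marks a significant improvement.  Points for an accepted predictor come from
dividing its odds ratio by the per-point odds ratio of the base score and
rounding to the nearest 0.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .cohort import Cohort
from .errors import DesignError, FitError, InvalidInputError, SeparationError

__all__ = [
    "FittedLogistic",
    "CandidateScanRow",
    "ScoreAssignment",
    "fit_logistic",
    "recalibrate_extend",
    "candidate_scan",
    "delta_aic_significant",
    "assign_score_points",
    "vif",
]

logger = logging.getLogger(__name__)

_MAX_ITER = 100
_GTOL = 1e-8
_LLTOL = 1e-10
_COEF_BOUND = 30.0  # |coef| beyond this on standardised-ish designs => separation


@dataclass(frozen=True)
class FittedLogistic:
    """Maximum-likelihood logistic fit: coefficients (intercept first),
    covariance (inverse observed information), log-likelihood, and AIC."""

    coefficients: np.ndarray
    covariance: np.ndarray
    loglik: float
    aic: float
    n: int
    converged: bool
    names: tuple[str, ...] = ()

    @property
    def k(self) -> int:
        return self.coefficients.size

    def predict(self, design: np.ndarray,
                offset: Optional[np.ndarray] = None) -> np.ndarray:
        X = _with_intercept(np.asarray(design, dtype=float))
        lp = X @ self.coefficients
        if offset is not None:
            lp = lp + offset
        return expit(lp)

    def wald_ci(self, j: int, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm
        se = math.sqrt(self.covariance[j, j])
        z = norm.ppf(0.5 + level / 2.0)
        b = self.coefficients[j]
        return b - z * se, b + z * se


def _with_intercept(design: np.ndarray) -> np.ndarray:
    if design.ndim == 1:
        design = design.reshape(-1, 1)
    return np.column_stack([np.ones(design.shape[0]), design])


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
            offset: np.ndarray) -> float:
    lp = X @ beta + offset
    # stable log(1+exp(lp)) - y*lp
    return float(np.sum(y * lp - np.logaddexp(0.0, lp)))


def fit_logistic(design: np.ndarray, y: Sequence[int],
                 offset: Optional[np.ndarray] = None,
                 names: Sequence[str] = ()) -> FittedLogistic:
    """Fit a logistic regression of ``y`` on ``design`` (intercept added).

    ``offset`` enters the linear predictor with a fixed coefficient of 1.
    Raises :class:`SeparationError` on (quasi-)complete separation or a
    one-class outcome, :class:`DesignError` on a rank-deficient design.
    """
    X0 = np.asarray(design, dtype=float)
    if X0.ndim == 1:
        X0 = X0.reshape(-1, 1)
    y = np.asarray(y, dtype=float)
    if X0.shape[0] != y.size:
        raise InvalidInputError("design and y lengths differ")
    if not np.isin(y, (0.0, 1.0)).all():
        raise InvalidInputError("y must be binary 0/1")
    if y.min() == y.max():
        raise SeparationError("outcome is constant; logistic fit is degenerate")
    X = _with_intercept(X0)
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise DesignError("design matrix is rank deficient")
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    beta = np.zeros(k)
    ll = _loglik(X, y, beta, off)
    converged = False
    for _ in range(_MAX_ITER):
        lp = X @ beta + off
        p = expit(lp)
        grad = X.T @ (y - p)
        w = p * (1.0 - p)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix (separation?)") from exc
        # step halving keeps the log-likelihood monotone
        t = 1.0
        for _ in range(60):
            cand = beta + t * step
            ll_new = _loglik(X, y, cand, off)
            if ll_new >= ll:
                break
            t /= 2.0
        else:
            break
        beta = cand
        improved = ll_new - ll
        ll = ll_new
        if np.linalg.norm(X.T @ (y - expit(X @ beta + off))) <= _GTOL:
            converged = True
            break
        if improved <= _LLTOL * (abs(ll) + 1.0):
            converged = True
            break
    if np.max(np.abs(beta)) > _COEF_BOUND:
        raise SeparationError(
            "coefficients diverged; data are (quasi-)separated")
    if not converged:
        raise FitError("logistic fit did not converge in "
                       f"{_MAX_ITER} iterations")
    p = expit(X @ beta + off)
    w = p * (1.0 - p)
    H = X.T @ (X * w[:, None])
    cov = np.linalg.inv(H)
    aic = 2.0 * k - 2.0 * ll
    return FittedLogistic(coefficients=beta, covariance=cov, loglik=ll,
                          aic=aic, n=n, converged=True,
                          names=("intercept", *names) if names
                          else ("intercept",) + tuple(
                              f"x{j}" for j in range(k - 1)))


def fit_intercept_only(y: Sequence[int],
                       offset: Optional[np.ndarray] = None) -> FittedLogistic:
    """Intercept-only logistic fit (optionally with a fixed offset)."""
    y = np.asarray(y, dtype=float)
    return fit_logistic(np.empty((y.size, 0)), y, offset=offset)


def recalibrate_extend(score: Sequence[float],
                       extras: Optional[np.ndarray] = None,
                       y: Sequence[int] = (),
                       extra_names: Sequence[str] = ()) -> FittedLogistic:
    """Refit intercept and a single slope on the base score and add new
    binary predictors; the score's internal component weights are never
    re-estimated.

    ``extras`` is an (n, m) column matrix (m may be 0 for pure
    recalibration).
    """
    score = np.asarray(score, dtype=float).reshape(-1, 1)
    if extras is None or (hasattr(extras, "size") and np.asarray(extras).size == 0):
        design = score
        names = ("score",)
    else:
        extras = np.asarray(extras, dtype=float)
        if extras.ndim == 1:
            extras = extras.reshape(-1, 1)
        design = np.column_stack([score, extras])
        names = ("score",) + (tuple(extra_names) or tuple(
            f"extra{j}" for j in range(extras.shape[1])))
    return fit_logistic(design, y, names=names)


@dataclass(frozen=True)
class CandidateScanRow:
    """One row of the one-at-a-time candidate scan."""

    candidate: str
    auc: Optional[float]
    aic: Optional[float]
    delta_aic: Optional[float]
    significant: bool
    fitted: bool = True


def _apparent_auc(p: np.ndarray, y: np.ndarray) -> float:
    from .performance import c_statistic
    return c_statistic(p, y)


def candidate_scan(cohort: Cohort, base_score: Sequence[float],
                   candidates: Sequence[str]) -> list[CandidateScanRow]:
    """AIC and apparent AUC of base+candidate for each candidate field.

    Includes a base row named ``"None"``; rows are sorted by AIC ascending
    with unfitted (zero-variance) candidates last.  Significance is an AIC
    drop greater than 10 versus the base model.
    """
    y = cohort.outcomes()
    score = np.asarray(base_score, dtype=float)
    base_fit = recalibrate_extend(score, None, y)
    base_p = base_fit.predict(score.reshape(-1, 1))
    rows = [CandidateScanRow("None", _apparent_auc(base_p, y), base_fit.aic,
                             0.0, False)]
    for name in candidates:
        x = cohort.column(name).astype(float)
        if np.ptp(x) == 0:
            logger.warning("candidate %r has zero variance; not fitted", name)
            rows.append(CandidateScanRow(name, None, None, None, False,
                                         fitted=False))
            continue
        fit = recalibrate_extend(score, x.reshape(-1, 1), y,
                                 extra_names=(name,))
        p = fit.predict(np.column_stack([score, x]))
        delta = base_fit.aic - fit.aic
        rows.append(CandidateScanRow(name, _apparent_auc(p, y), fit.aic,
                                     delta,
                                     delta_aic_significant(base_fit.aic,
                                                           fit.aic)))
    fitted = sorted((r for r in rows if r.fitted), key=lambda r: r.aic)
    return fitted + [r for r in rows if not r.fitted]


def delta_aic_significant(aic_base: float, aic_candidate: float) -> bool:
    """True when the candidate improves AIC by more than 10."""
    if not (math.isfinite(aic_base) and math.isfinite(aic_candidate)):
        raise InvalidInputError("AIC values must be finite")
    return aic_base - aic_candidate > 10.0


@dataclass(frozen=True)
class ScoreAssignment:
    """Points assigned to a new predictor from the odds-ratio division rule."""

    or_new: float
    or_per_point: float
    raw_ratio: float
    points: float


def _round_half_grid(x: float) -> float:
    # nearest 0.5 increment, ties away from zero
    return math.copysign(math.floor(abs(x) * 2.0 + 0.5) / 2.0, x)


def assign_score_points(or_new: float, or_per_point: float,
                        log_scale: bool = False) -> ScoreAssignment:
    """Points for a new predictor: its odds ratio divided by the per-point
    odds ratio of the base score, rounded to the nearest 0.5 increment.

    ``log_scale=True`` instead divides the log odds ratios (the additive
    alternative); the default follows the published division of raw ORs.
    """
    if or_new <= 0 or or_per_point <= 0:
        raise InvalidInputError("odds ratios must be positive")
    if log_scale:
        raw = math.log(or_new) / math.log(or_per_point)
    else:
        raw = or_new / or_per_point
    return ScoreAssignment(or_new, or_per_point, raw, _round_half_grid(raw))


def vif(design: np.ndarray, names: Sequence[str] = ()) -> dict[str, float]:
    """Variance inflation factors from regressing each predictor on the rest.

    Exact collinearity yields ``inf`` for the affected predictors rather
    than raising.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise InvalidInputError("need at least two predictor columns")
    n, k = X.shape
    labels = tuple(names) or tuple(f"x{j}" for j in range(k))
    out: dict[str, float] = {}
    for j in range(k):
        target = X[:, j]
        others = _with_intercept(np.delete(X, j, axis=1))
        coef, res, rank, _ = np.linalg.lstsq(others, target, rcond=None)
        fitted = others @ coef
        ss_tot = float(np.sum((target - target.mean()) ** 2))
        ss_res = float(np.sum((target - fitted) ** 2))
        if ss_tot == 0:
            out[labels[j]] = float("inf")
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[labels[j]] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out
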