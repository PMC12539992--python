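"""Univariate screening battery: 2x2 odds ratios with Woolf intervals,
Fisher's exact test, Mann-Whitney U, and per-unit logistic odds ratios."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DRUG_FLAGS, Cohort
from .errors import InvalidInputError
from .update import fit_logistic

__all__ = [
    "TwoByTwo",
    "ORResult",
    "odds_ratio_2x2",
    "fisher_exact_two_sided",
    "mann_whitney_u",
    "univariate_logistic_or",
    "two_by_two_from_cohort",
    "univariate_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TwoByTwo:
    """Outcome-by-exposure contingency counts."""

    event_exposed: int
    event_unexposed: int
    nonevent_exposed: int
    nonevent_unexposed: int

    def __post_init__(self) -> None:
        for name in ("event_exposed", "event_unexposed", "nonevent_exposed",
                     "nonevent_unexposed"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.event_exposed, self.event_unexposed,
                self.nonevent_exposed, self.nonevent_unexposed)

    def as_array(self) -> np.ndarray:
        # rows = exposure, cols = outcome, for scipy
        return np.array([[self.event_exposed, self.nonevent_exposed],
                         [self.event_unexposed, self.nonevent_unexposed]])


@dataclass(frozen=True)
class ORResult:
    """Odds ratio with its interval and p-value.

    ``defined`` is false when a zero cell makes the cross-product ratio
    degenerate; no continuity correction is applied.
    """

    odds_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p: Optional[float]
    method: str
    defined: bool = True


def odds_ratio_2x2(t: TwoByTwo, ci_level: float = 0.95) -> ORResult:
    """Cross-product odds ratio with the Woolf (log-normal) interval.

    A zero cell yields an undefined result flagged rather than raised.
    """
    a, b, c, d = t.cells
    p = fisher_exact_two_sided(t)
    if min(a, b, c, d) == 0:
        return ORResult(None, None, None, p, "woolf_2x2", defined=False)
    oratio = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    log_or = math.log(oratio)
    return ORResult(oratio, math.exp(log_or - z * se),
                    math.exp(log_or + z * se), p, "woolf_2x2")


def fisher_exact_two_sided(t: TwoByTwo) -> float:
    """Two-sided Fisher exact p (probability-mass method)."""
    return float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])


def mann_whitney_u(group_a: Sequence[float],
                   group_b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U for ``group_a`` vs ``group_b``.

    Midrank tie handling; two-sided p from the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def univariate_logistic_or(x: Sequence[float], y: Sequence[int],
                           ci_level: float = 0.95) -> ORResult:
    """Per-unit odds ratio from a single-covariate logistic MLE with Wald CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.size != y.size or x.size < 2:
        raise InvalidInputError("x and y must share a length of at least 2")
    design = x.reshape(-1, 1)
    fit = fit_logistic(design, y)
    beta = fit.coefficients[1]
    se = math.sqrt(fit.covariance[1, 1])
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else float("nan")
    return ORResult(math.exp(beta), math.exp(beta - z * se),
                    math.exp(beta + z * se), p, "logistic")


def two_by_two_from_cohort(cohort: Cohort, exposure_field: str) -> TwoByTwo:
    """Cross-tabulate the classified outcome against a binary cohort column."""
    y = cohort.outcomes()
    x = cohort.column(exposure_field)
    return TwoByTwo(
        event_exposed=int(np.sum((y == 1) & (x == 1))),
        event_unexposed=int(np.sum((y == 1) & (x == 0))),
        nonevent_exposed=int(np.sum((y == 0) & (x == 1))),
        nonevent_unexposed=int(np.sum((y == 0) & (x == 0))),
    )


_CONTINUOUS = ("age", "weight_kg", "albumin_gdl", "cddp_dose_mg", "scr_baseline")
_BINARY = ("male", "hypertension", "diabetes", "sh", "no_mg") + DRUG_FLAGS


def _median_iqr(v: np.ndarray) -> str:
    if v.size == 0:
        return "-"
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return f"{med:g} ({q1:g}-{q3:g})"


def univariate_table(cohort: Cohort,
                     continuous: Sequence[str] = _CONTINUOUS,
                     binary: Sequence[str] = _BINARY) -> pd.DataFrame:
    """One screening row per covariate, mirroring the published layout.

    Binary covariates use the 2x2 odds ratio and Fisher's exact test;
    continuous covariates use a per-unit logistic odds ratio and the
    Mann-Whitney U test.  Covariates with zero variance are omitted with a
    log message; a zero cell flags the row undefined ("-").
    """
    y = cohort.outcomes()
    rows = []
    for name in continuous:
        x = cohort.column(name)
        if np.ptp(x) == 0:
            logger.info("omitting constant covariate %r", name)
            continue
        _, p_mw = mann_whitney_u(x[y == 1], x[y == 0])
        res = univariate_logistic_or(x, y)
        rows.append({
            "covariate": name, "type": "continuous",
            "summary_event": _median_iqr(x[y == 1]),
            "summary_nonevent": _median_iqr(x[y == 0]),
            "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "p": p_mw, "defined": True,
        })
    for name in binary:
        x = cohort.column(name)
        if np.ptp(x) == 0:
            logger.info("omitting constant covariate %r", name)
            continue
        t = two_by_two_from_cohort(cohort, name)
        res = odds_ratio_2x2(t)
        rows.append({
            "covariate": name, "type": "binary",
            "summary_event": f"{t.event_exposed}",
            "summary_nonevent": f"{t.nonevent_exposed}",
            "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "p": res.p, "defined": res.defined,
        })
    return pd.DataFrame(rows)
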