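"""Points-based risk score: weights table, logistic anchor, and risk bands."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.special import expit

from .cohort import Cohort, PatientRecord
from .errors import InvalidInputError

__all__ = [
    "ScoreWeights",
    "ScoreModel",
    "motwani_score",
    "updated_score",
    "score_record",
    "coefficients_from_anchor",
    "predict_probability",
    "score_band",
    "probability_band",
    "band_incidence",
]

BANDS = ("low", "intermediate", "high")


@dataclass(frozen=True)
class ScoreWeights:
    """Bin points for the four base covariates plus optional extension terms.

    Extension terms map a derived predicate name (resolved through
    :meth:`akiscore.cohort.Cohort.column`, e.g. ``no_mg``) to the points added
    when the predicate holds.
    """

    age_bins: tuple[tuple[float, float], ...] = ((60.0, 0.0), (70.0, 1.5),
                                                 (math.inf, 2.5))
    albumin_cut: float = 3.5
    albumin_points: float = 2.0
    dose_bins: tuple[tuple[float, float], ...] = ((100.0, 0.0), (150.0, 1.0),
                                                  (math.inf, 3.0))
    hypertension_points: float = 2.0
    extensions: dict[str, float] = field(default_factory=dict)

    def base_score(self, age: float, albumin: float, dose: float,
                   hypertension: bool) -> float:
        total = 0.0
        for upper, pts in self.age_bins:
            if age <= upper:
                total += pts
                break
        if albumin <= self.albumin_cut:
            total += self.albumin_points
        for upper, pts in self.dose_bins:
            if dose <= upper:
                total += pts
                break
        if hypertension:
            total += self.hypertension_points
        return total


#: Default weights: the published four-factor points table.
DEFAULT_WEIGHTS = ScoreWeights()

#: Weights extended with the no-magnesium term worth 3.0 points.
UPDATED_WEIGHTS = ScoreWeights(extensions={"no_mg": 3.0})


@dataclass(frozen=True)
class ScoreModel:
    """A points table plus the logistic anchor mapping score to probability."""

    weights: ScoreWeights
    intercept: float
    slope: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "weights": {
                "age_bins": [list(b) for b in self.weights.age_bins],
                "albumin_cut": self.weights.albumin_cut,
                "albumin_points": self.weights.albumin_points,
                "dose_bins": [list(b) for b in self.weights.dose_bins],
                "hypertension_points": self.weights.hypertension_points,
                "extensions": dict(self.weights.extensions),
            },
            "intercept": self.intercept,
            "slope": self.slope,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ScoreModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        w = payload["weights"]
        inf = math.inf
        weights = ScoreWeights(
            age_bins=tuple((b[0] if b[0] is not None else inf, b[1])
                           for b in w["age_bins"]),
            albumin_cut=w["albumin_cut"],
            albumin_points=w["albumin_points"],
            dose_bins=tuple((b[0] if b[0] is not None else inf, b[1])
                            for b in w["dose_bins"]),
            hypertension_points=w["hypertension_points"],
            extensions=dict(w["extensions"]),
        )
        return cls(weights=weights, intercept=payload["intercept"],
                   slope=payload["slope"])


def motwani_score(age: float, albumin: float, cddp_dose: float,
                  hypertension: bool,
                  weights: ScoreWeights = DEFAULT_WEIGHTS) -> float:
    """Base points from the four-factor table; values lie on the 0.5 grid
    between 0 and 9.5."""
    return weights.base_score(age, albumin, cddp_dose, hypertension)


def updated_score(base_points: float, mg_supplement: bool,
                  no_mg_points: float = 3.0) -> float:
    """Extend the base score with the no-magnesium term (max 12.5)."""
    return base_points if mg_supplement else base_points + no_mg_points


def score_record(record: PatientRecord,
                 weights: ScoreWeights = DEFAULT_WEIGHTS) -> float:
    """Total score for one patient under ``weights`` (base + extensions)."""
    total = weights.base_score(record.age, record.albumin_gdl,
                               record.cddp_dose_mg, record.hypertension)
    for predicate, pts in weights.extensions.items():
        if predicate == "no_mg":
            flag = not record.mg_supplement
        elif predicate == "sh":
            flag = record.short_hydration
        elif predicate == "male":
            flag = record.male
        elif predicate in record.drugs:
            flag = record.drugs[predicate]
        else:
            flag = bool(getattr(record, predicate))
        if flag:
            total += pts
    return total


def _weights_key(weights: ScoreWeights) -> tuple:
    return (weights.age_bins, weights.albumin_cut, weights.albumin_points,
            weights.dose_bins, weights.hypertension_points,
            tuple(sorted(weights.extensions.items())))


def cohort_scores(cohort: Cohort,
                  weights: ScoreWeights = DEFAULT_WEIGHTS) -> np.ndarray:
    """Vectorised per-patient scores; agrees with :func:`score_record`
    element-wise and is cached on the cohort."""
    key = ("__scores__", _weights_key(weights))
    cached = cohort._cache.get(key)
    if cached is not None:
        return cached
    total = np.zeros(len(cohort))
    for column, bins in (("age", weights.age_bins),
                         ("cddp_dose_mg", weights.dose_bins)):
        values = cohort.column(column)
        prev = -math.inf
        for upper, pts in bins:
            total += pts * ((values > prev) & (values <= upper))
            prev = upper
    total += weights.albumin_points * \
        (cohort.column("albumin_gdl") <= weights.albumin_cut)
    total += weights.hypertension_points * cohort.column("hypertension")
    for predicate, pts in weights.extensions.items():
        total += pts * cohort.column(predicate)
    cohort._cache[key] = total
    return total


def coefficients_from_anchor(p0: float, or_per_point: float) -> tuple[float, float]:
    """Reconstruct (intercept, slope) from a baseline probability at score 0
    and a per-point odds ratio."""
    if not 0.0 < p0 < 1.0:
        raise InvalidInputError("p0 must lie strictly between 0 and 1")
    if not or_per_point > 0:
        raise InvalidInputError("or_per_point must be positive")
    return math.log(p0 / (1.0 - p0)), math.log(or_per_point)


def predict_probability(model: ScoreModel, points) -> float | np.ndarray:
    """Probability of the outcome at a given score under the model's anchor."""
    lp = model.intercept + model.slope * np.asarray(points, dtype=float)
    out = expit(lp)
    return float(out) if out.ndim == 0 else out


def score_band(points: float, cutpoints: tuple[float, float] = (4.0, 7.0)) -> str:
    """Risk band from score points (low below 4, high at or above 7)."""
    lo, hi = cutpoints
    if points < lo:
        return "low"
    if points < hi:
        return "intermediate"
    return "high"


def probability_band(p: float, cutpoints: tuple[float, float] = (0.10, 0.20)) -> str:
    """Risk band from a predicted probability; boundaries assigned upward."""
    lo, hi = cutpoints
    if p < lo:
        return "low"
    if p < hi:
        return "intermediate"
    return "high"


def band_incidence(cohort: Cohort,
                   score_fn: Callable[[PatientRecord], float],
                   cutpoints: tuple[float, float] = (4.0, 7.0),
                   ) -> dict[str, dict[str, float | int | None]]:
    """Event counts, sizes, and rates per score band.

    An empty band reports ``rate=None`` (undefined) rather than raising.
    """
    counts = {b: {"events": 0, "total": 0} for b in BANDS}
    for rec in cohort:
        band = score_band(score_fn(rec), cutpoints)
        counts[band]["total"] += 1
        counts[band]["events"] += int(rec.outcome.aki)
    out: dict[str, dict[str, float | int | None]] = {}
    for b in BANDS:
        total = counts[b]["total"]
        events = counts[b]["events"]
        rate = events / total if total else None
        out[b] = {"events": events, "total": total, "rate": rate}
    return out
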