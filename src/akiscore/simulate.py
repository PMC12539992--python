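"""Seeded synthetic cohorts matching the published covariate marginals.

Covariates are drawn independently (the study reports no correlation
structure); continuous covariates use log-normal distributions whose two
parameters are solved from the printed median and interquartile range.  The
outcome is drawn from a logistic model on the base risk score plus a
no-magnesium term, and the follow-up creatinine is then constructed so that
outcome classification reproduces the drawn label exactly.

Each field draws from its own child random stream keyed by (root seed, field
name), so adding a field never perturbs existing draws.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from . import published
from .cohort import DRUG_FLAGS, Cohort, PatientRecord
from .errors import ConfigError, InvalidInputError
from .score import motwani_score

__all__ = [
    "TrueOutcomeParams",
    "GeneratorConfig",
    "table3_defaults",
    "default_config",
    "generate_cohort",
    "cohort_from_2x2",
]

_Z75 = norm.ppf(0.75)  # 0.6744897...


@dataclass(frozen=True)
class TrueOutcomeParams:
    """True logistic coefficients of the outcome-generating model.

    Defaults reconstruct the published fit: intercept odds 0.04, odds ratio
    1.29 per base-score point, odds ratio 3.91 for no magnesium supplement.
    """

    intercept: float = math.log(published.ANCHOR_P0)  # ln 0.04 = -3.2189
    beta_score: float = math.log(published.OR_PER_POINT)  # ln 1.29
    beta_no_mg: float = math.log(published.OR_NO_MG)  # ln 3.91

    def __post_init__(self) -> None:
        for name in ("intercept", "beta_score", "beta_no_mg"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")

    def probability(self, score, no_mg) -> np.ndarray:
        lp = (self.intercept + self.beta_score * np.asarray(score, dtype=float)
              + self.beta_no_mg * np.asarray(no_mg, dtype=float))
        return expit(lp)


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling configuration; defaults emulate the published cohort."""

    n: int = published.N_TOTAL
    p_male: float = published.PREVALENCE["male"]
    p_htn: float = published.PREVALENCE["hypertension"]
    p_dm: float = published.PREVALENCE["diabetes"]
    p_no_mg: float = published.PREVALENCE["no_mg"]
    p_sh: float = published.PREVALENCE["sh"]
    age_dist: tuple[float, float, float] = published.CONTINUOUS_DISTS["age"]
    weight_dist: tuple[float, float, float] = published.CONTINUOUS_DISTS["weight_kg"]
    albumin_dist: tuple[float, float, float] = published.CONTINUOUS_DISTS["albumin_gdl"]
    dose_dist: tuple[float, float, float] = published.CONTINUOUS_DISTS["cddp_dose_mg"]
    scr_baseline_dist: tuple[float, float, float] = published.CONTINUOUS_DISTS["scr_baseline"]
    drug_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(published.DRUG_PREVALENCE))
    true_params: TrueOutcomeParams = field(default_factory=TrueOutcomeParams)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigError("n must be >= 0")
        for name in ("p_male", "p_htn", "p_dm", "p_no_mg", "p_sh"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        for drug, p in self.drug_prevalence.items():
            if drug not in DRUG_FLAGS:
                raise ConfigError(f"unknown drug flag {drug!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"prevalence of {drug!r} outside [0, 1]")
        for name in ("age_dist", "weight_dist", "albumin_dist", "dose_dist",
                     "scr_baseline_dist"):
            med, q1, q3 = getattr(self, name)
            if not (0 < q1 <= med <= q3):
                raise ConfigError(f"{name}: need 0 < q1 <= median <= q3")


def table3_defaults() -> GeneratorConfig:
    """Configuration whose marginals equal the published cohort table
    (n=1785, 19.7% no magnesium, 69.0% male, ...)."""
    return GeneratorConfig()


# alias with a neutral name for callers that prefer it
default_config = table3_defaults


def _stream(seed: int, name: str) -> np.random.Generator:
    """Child RNG keyed by (seed, field name): stable under field addition."""
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng([int(seed), key])


def _lognormal(rng: np.random.Generator, dist: tuple[float, float, float],
               size: int) -> np.ndarray:
    """Log-normal draws matching a printed (median, q1, q3)."""
    med, q1, q3 = dist
    mu = math.log(med)
    sigma = math.log(q3 / q1) / (2.0 * _Z75) if q3 > q1 else 0.0
    return np.exp(rng.normal(mu, sigma, size=size))


def generate_cohort(config: GeneratorConfig, seed: int,
                    ) -> tuple[Cohort, np.ndarray]:
    """Draw a cohort and return it with each patient's true event probability.

    Deterministic given ``(config, seed)``.  The follow-up creatinine is
    constructed from the drawn outcome (events get an increase >= 0.3 mg/dL,
    non-events an increase in [0, 0.3)), so classifying the creatinine pair
    reproduces the drawn label for every patient.
    """
    if not isinstance(seed, (int, np.integer)):
        raise ConfigError("seed must be an integer")
    n = config.n
    if n == 0:
        return Cohort(records=[], provenance="synthetic", seed=int(seed)), \
            np.zeros(0)

    sex = np.where(_stream(seed, "sex").random(n) < config.p_male, "M", "F")
    age = np.clip(np.rint(_lognormal(_stream(seed, "age"), config.age_dist, n)),
                  20, 110).astype(int)
    weight = np.clip(_lognormal(_stream(seed, "weight"), config.weight_dist, n),
                     25.0, 160.0)
    albumin = np.clip(_lognormal(_stream(seed, "albumin"), config.albumin_dist, n),
                      1.0, 6.0)
    dose = np.clip(_lognormal(_stream(seed, "dose"), config.dose_dist, n),
                   10.0, 400.0)
    scr = np.clip(_lognormal(_stream(seed, "scr_baseline"),
                             config.scr_baseline_dist, n), 0.2, 5.0)
    htn = _stream(seed, "hypertension").random(n) < config.p_htn
    dm = _stream(seed, "diabetes").random(n) < config.p_dm
    mg = _stream(seed, "mg_supplement").random(n) >= config.p_no_mg
    sh = _stream(seed, "short_hydration").random(n) < config.p_sh

    hyd = _stream(seed, "hydration_values")
    volume = np.where(sh, hyd.uniform(1.5, 2.9, n), hyd.uniform(3.0, 5.0, n))
    duration = np.where(sh, hyd.uniform(3.0, 4.9, n), hyd.uniform(5.0, 8.0, n))

    drugs = {}
    for name in DRUG_FLAGS:
        p = config.drug_prevalence.get(name, 0.0)
        drugs[name] = _stream(seed, f"drug:{name}").random(n) < p

    base_score = np.array([
        motwani_score(int(a), float(alb), float(d), bool(h))
        for a, alb, d, h in zip(age, albumin, dose, htn)
    ])
    p_true = config.true_params.probability(base_score, ~mg)
    event = _stream(seed, "outcome").random(n) < p_true

    out_rng = _stream(seed, "scr_followup")
    increase = np.where(event,
                        0.3 + out_rng.exponential(0.25, n),
                        out_rng.uniform(0.0, 0.2999, n))
    followup = scr + increase

    records = [
        PatientRecord(
            id=f"S{i:06d}",
            age=int(age[i]),
            sex=str(sex[i]),
            weight_kg=float(weight[i]),
            albumin_gdl=float(albumin[i]),
            cddp_dose_mg=float(dose[i]),
            hypertension=bool(htn[i]),
            diabetes=bool(dm[i]),
            mg_supplement=bool(mg[i]),
            infusion_volume_l=float(volume[i]),
            infusion_duration_h=float(duration[i]),
            scr_baseline=float(scr[i]),
            scr_followup_max14d=float(followup[i]),
            drugs={d: bool(drugs[d][i]) for d in DRUG_FLAGS},
        )
        for i in range(n)
    ]
    return Cohort(records=records, provenance="synthetic", seed=int(seed)), p_true


_EXPOSURE_SETTERS = {
    "no_mg": lambda kw, flag: kw.update(mg_supplement=not flag),
    "male": lambda kw, flag: kw.update(sex="M" if flag else "F"),
    "sh": lambda kw, flag: kw.update(
        infusion_volume_l=2.0 if flag else 4.0,
        infusion_duration_h=4.0 if flag else 6.0),
    "hypertension": lambda kw, flag: kw.update(hypertension=flag),
    "diabetes": lambda kw, flag: kw.update(diabetes=flag),
}


def cohort_from_2x2(event_exposed: int, event_unexposed: int,
                    nonevent_exposed: int, nonevent_unexposed: int,
                    exposure_field: str) -> Cohort:
    """Minimal cohort whose outcome-by-exposure cross-tabulation equals the
    given counts exactly; all other fields take fixed valid defaults.

    ``exposure_field`` may be a drug flag or one of ``no_mg``, ``male``,
    ``sh``, ``hypertension``, ``diabetes``.
    """
    counts = (event_exposed, event_unexposed, nonevent_exposed,
              nonevent_unexposed)
    if any(c < 0 for c in counts):
        raise InvalidInputError("counts must be non-negative")
    if exposure_field not in _EXPOSURE_SETTERS and exposure_field not in DRUG_FLAGS:
        raise InvalidInputError(f"unknown exposure field {exposure_field!r}")

    records: list[PatientRecord] = []
    i = 0
    for event, exposed, count in (
        (True, True, event_exposed),
        (True, False, event_unexposed),
        (False, True, nonevent_exposed),
        (False, False, nonevent_unexposed),
    ):
        for _ in range(count):
            kw: dict = dict(
                id=f"T{i:06d}", age=60, sex="M", weight_kg=60.0,
                albumin_gdl=4.0, cddp_dose_mg=100.0, hypertension=False,
                diabetes=False, mg_supplement=True, infusion_volume_l=4.0,
                infusion_duration_h=6.0, scr_baseline=0.7,
                scr_followup_max14d=1.1 if event else 0.8, drugs={},
            )
            if exposure_field in DRUG_FLAGS:
                kw["drugs"] = {exposure_field: exposed}
            else:
                _EXPOSURE_SETTERS[exposure_field](kw, exposed)
            records.append(PatientRecord(**kw))
            i += 1
    return Cohort(records=records, provenance="synthetic")
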