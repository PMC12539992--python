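"""Patient and cohort domain types, clinical derivation rules, and CSV I/O.

A :class:`PatientRecord` carries the covariates needed to score a patient,
the exposure flags examined as candidate predictors, and the creatinine pair
from which the acute-kidney-injury outcome is classified.  Cohort files are
plain UTF-8 CSV with a fixed schema (see :data:`CSV_COLUMNS`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CohortSchemaError, InvalidInputError

__all__ = [
    "DRUG_FLAGS",
    "CSV_COLUMNS",
    "PatientRecord",
    "Cohort",
    "AkiOutcome",
    "classify_aki",
    "cockcroft_gault_clcr",
    "ckd_epi_egfr",
    "short_hydration_flag",
    "pre_existing_ckd",
    "read_cohort_csv",
    "write_cohort_csv",
]

#: Concomitant-drug exposure flags carried by every record, in column order.
DRUG_FLAGS: tuple[str, ...] = (
    "capecitabine",
    "cpa",
    "cpt11",
    "dtx",
    "dxr",
    "gem",
    "mtx",
    "pem",
    "ptx",
    "s1",
    "vnr",
    "vp16",
    "fu5",
    "egfri",
    "vegf",
    "cpi",
)

_BASE_COLUMNS: tuple[str, ...] = (
    "id",
    "age",
    "sex",
    "weight_kg",
    "albumin_gdl",
    "cddp_dose_mg",
    "hypertension",
    "diabetes",
    "mg_supplement",
    "infusion_volume_l",
    "infusion_duration_h",
    "scr_baseline",
    "scr_followup_max14d",
)

#: Exact header of a cohort CSV file.
CSV_COLUMNS: tuple[str, ...] = _BASE_COLUMNS + DRUG_FLAGS

_BOOL_FIELDS = ("hypertension", "diabetes", "mg_supplement") + DRUG_FLAGS


@dataclass(frozen=True)
class PatientRecord:
    """One patient's covariates, exposures, and outcome material.

    Creatinine values are in mg/dL; ``scr_baseline`` is the value closest to
    first administration within the preceding 30 days, ``scr_followup_max14d``
    the maximum within 14 days after the first dose.
    """

    id: str
    age: int
    sex: Literal["M", "F"]
    weight_kg: float
    albumin_gdl: float
    cddp_dose_mg: float
    hypertension: bool
    diabetes: bool
    mg_supplement: bool
    infusion_volume_l: float
    infusion_duration_h: float
    scr_baseline: float
    scr_followup_max14d: float
    drugs: dict[str, bool] = field(default_factory=dict)
    height_cm: Optional[float] = None  # optional, not serialised to CSV

    def __post_init__(self) -> None:
        if self.age < 20:
            raise InvalidInputError(f"patient {self.id}: age {self.age} < 20")
        if self.sex not in ("M", "F"):
            raise InvalidInputError(f"patient {self.id}: sex must be 'M' or 'F'")
        for name in ("weight_kg", "albumin_gdl", "cddp_dose_mg", "scr_baseline",
                     "scr_followup_max14d"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(
                    f"patient {self.id}: {name} must be strictly positive")
        if self.infusion_volume_l < 0 or self.infusion_duration_h < 0:
            raise InvalidInputError(
                f"patient {self.id}: infusion volume/duration must be >= 0")
        if self.height_cm is not None and not self.height_cm > 0:
            raise InvalidInputError(f"patient {self.id}: height must be > 0")
        unknown = set(self.drugs) - set(DRUG_FLAGS)
        if unknown:
            raise InvalidInputError(
                f"patient {self.id}: unknown drug flags {sorted(unknown)}")
        # normalise: every flag present, missing ones default to False
        full = {name: bool(self.drugs.get(name, False)) for name in DRUG_FLAGS}
        object.__setattr__(self, "drugs", full)

    @property
    def male(self) -> bool:
        return self.sex == "M"

    @property
    def short_hydration(self) -> bool:
        return short_hydration_flag(self.infusion_volume_l, self.infusion_duration_h)

    @property
    def outcome(self) -> "AkiOutcome":
        return classify_aki(self.scr_baseline, self.scr_followup_max14d)


@dataclass(frozen=True)
class AkiOutcome:
    """Outcome classification for one patient.

    ``akin_stage`` is 0 when no injury occurred, otherwise 1-3 by the
    fold-change of follow-up over baseline creatinine.
    """

    aki: bool
    akin_stage: int
    scr_increase: float
    fold_change: float


@dataclass
class Cohort:
    """An ordered collection of patients with unique ids.

    Column and outcome vectors are cached after first access; records are
    immutable so the cache stays valid as long as ``records`` is not
    reassigned.
    """

    records: list[PatientRecord]
    provenance: Literal["observed", "synthetic"] = "observed"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise CohortSchemaError(f"duplicate patient id {dup!r}")
        self._cache: dict = {}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    def outcomes(self) -> np.ndarray:
        """Binary outcome vector (1 = injury) classified from creatinine."""
        cached = self._cache.get("__outcomes__")
        if cached is None:
            # vectorised form of classify_aki's event rule
            increase = self.column("scr_followup_max14d") - \
                self.column("scr_baseline")
            cached = (increase >= 0.3).astype(int)
            self._cache["__outcomes__"] = cached
        return cached

    def column(self, name: str) -> np.ndarray:
        """Extract a covariate/exposure column by name.

        Accepts record fields, drug flags, and the derived names ``male``,
        ``no_mg``, ``sh`` (short hydration).
        """
        cached = self._cache.get(name)
        if cached is not None:
            return cached
        recs = self.records
        if name == "male":
            vals = np.array([r.male for r in recs], dtype=int)
        elif name == "no_mg":
            vals = np.array([not r.mg_supplement for r in recs], dtype=int)
        elif name == "sh":
            vals = np.array([r.short_hydration for r in recs], dtype=int)
        elif name in DRUG_FLAGS:
            vals = np.array([r.drugs[name] for r in recs], dtype=int)
        elif name in _BASE_COLUMNS and name not in ("id", "sex"):
            vals = np.array([getattr(r, name) for r in recs], dtype=float)
            if name in _BOOL_FIELDS:
                vals = vals.astype(int)
        else:
            raise KeyError(f"unknown cohort column {name!r}")
        self._cache[name] = vals
        return vals

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {c: getattr(r, c) for c in _BASE_COLUMNS}
            row.update(r.drugs)
            rows.append(row)
        df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
        for c in _BOOL_FIELDS:
            df[c] = df[c].astype(int)
        return df

    def subset(self, indices: Sequence[int], reindex_ids: bool = False) -> "Cohort":
        """Select records by position (with replacement allowed).

        ``reindex_ids`` assigns fresh ids so bootstrap resamples keep the
        unique-id invariant.
        """
        recs = [self.records[i] for i in indices]
        if reindex_ids:
            recs = [replace(r, id=f"b{k:06d}") for k, r in enumerate(recs)]
        return Cohort(records=recs, provenance=self.provenance, seed=self.seed)


def take_unchecked(cohort: Cohort, indices: Sequence[int]) -> Cohort:
    """Positional take that shares record objects and reuses cached columns.

    Internal fast path for bootstrap resampling: ids may repeat, so the
    unique-id invariant is deliberately bypassed.  Records are immutable,
    which keeps sharing safe.
    """
    new = Cohort.__new__(Cohort)
    new.records = [cohort.records[i] for i in indices]
    new.provenance = cohort.provenance
    new.seed = cohort.seed
    idx = np.asarray(indices)
    new._cache = {k: v[idx] for k, v in cohort._cache.items()}
    return new


def classify_aki(scr_baseline: float, scr_followup_max14d: float) -> AkiOutcome:
    """Classify the injury outcome from a baseline/follow-up creatinine pair.

    Injury is an absolute increase of at least 0.3 mg/dL within the follow-up
    window.  Severity stage uses the fold-change over baseline: stage 1 below
    2.0-fold, stage 2 from 2.0- to 3.0-fold inclusive, stage 3 above 3.0-fold.
    """
    if not (scr_baseline > 0 and scr_followup_max14d > 0):
        raise InvalidInputError("creatinine values must be strictly positive")
    increase = scr_followup_max14d - scr_baseline
    fold = scr_followup_max14d / scr_baseline
    aki = increase >= 0.3
    if not aki:
        stage = 0
    elif fold < 2.0:
        stage = 1
    elif fold <= 3.0:
        stage = 2
    else:
        stage = 3
    return AkiOutcome(aki=aki, akin_stage=stage, scr_increase=increase,
                      fold_change=fold)


def cockcroft_gault_clcr(age: float, weight_kg: float, scr: float,
                         sex: str) -> float:
    """Estimated creatinine clearance (mL/min), Cockcroft-Gault."""
    if age >= 140:
        raise InvalidInputError("age must be below 140 years")
    if not (age > 0 and weight_kg > 0 and scr > 0):
        raise InvalidInputError("age, weight, and creatinine must be positive")
    clcr = (140.0 - age) * weight_kg / (72.0 * scr)
    if sex == "F":
        clcr *= 0.85
    elif sex != "M":
        raise InvalidInputError("sex must be 'M' or 'F'")
    return clcr


def ckd_epi_egfr(age: float, sex: str, scr: float) -> float:
    """Estimated GFR (mL/min/1.73 m^2), 2009 creatinine equation, race-free."""
    if not (age > 0 and scr > 0):
        raise InvalidInputError("age and creatinine must be positive")
    if sex == "F":
        kappa, alpha, sex_factor = 0.7, -0.329, 1.018
    elif sex == "M":
        kappa, alpha, sex_factor = 0.9, -0.411, 1.0
    else:
        raise InvalidInputError("sex must be 'M' or 'F'")
    ratio = scr / kappa
    return (141.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.209
            * 0.993 ** age * sex_factor)


def short_hydration_flag(infusion_volume_l: float,
                         infusion_duration_h: float) -> bool:
    """True when peri-dose hydration was under 3 L given in under 5 h."""
    if infusion_volume_l < 0 or infusion_duration_h < 0:
        raise InvalidInputError("infusion volume/duration must be >= 0")
    return infusion_volume_l < 3.0 and infusion_duration_h < 5.0


def pre_existing_ckd(egfr: float) -> bool:
    """True when baseline eGFR is below 60 mL/min/1.73 m^2."""
    if egfr < 0:
        raise InvalidInputError("egfr must be >= 0")
    return egfr < 60.0


def _parse_bool(value: object, row: int, column: str) -> bool:
    s = str(value).strip()
    if s in ("0", "1"):
        return s == "1"
    raise CohortSchemaError(
        f"row {row}, column {column!r}: expected 0/1, got {value!r}")


def read_cohort_csv(path: str | Path) -> Cohort:
    """Read a cohort CSV file, validating the schema strictly.

    Missing or unknown columns, duplicate ids, unparseable cells, and missing
    values all raise :class:`CohortSchemaError` naming the offending
    row/column.  Booleans are encoded 0/1, sex as ``M``/``F``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    missing = [c for c in CSV_COLUMNS if c not in cols]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {missing}")
    unknown = [c for c in cols if c not in CSV_COLUMNS]
    if unknown:
        raise CohortSchemaError(f"unknown column(s): {unknown}")

    records: list[PatientRecord] = []
    seen_ids: set[str] = set()
    float_fields = ("weight_kg", "albumin_gdl", "cddp_dose_mg",
                    "infusion_volume_l", "infusion_duration_h",
                    "scr_baseline", "scr_followup_max14d")
    for i, row in enumerate(df.itertuples(index=False)):
        raw = dict(zip(cols, row))
        pid = raw["id"]
        if pid == "":
            raise CohortSchemaError(f"row {i}, column 'id': empty id")
        if pid in seen_ids:
            raise CohortSchemaError(f"row {i}: duplicate id {pid!r}")
        seen_ids.add(pid)
        kwargs: dict = {"id": pid, "sex": raw["sex"]}
        try:
            kwargs["age"] = int(raw["age"])
        except ValueError as exc:
            raise CohortSchemaError(
                f"row {i}, column 'age': unparseable value {raw['age']!r}") from exc
        for name in float_fields:
            try:
                val = float(raw[name])
            except ValueError as exc:
                raise CohortSchemaError(
                    f"row {i}, column {name!r}: unparseable value "
                    f"{raw[name]!r}") from exc
            if math.isnan(val):
                raise CohortSchemaError(f"row {i}, column {name!r}: missing value")
            kwargs[name] = val
        for name in ("hypertension", "diabetes", "mg_supplement"):
            kwargs[name] = _parse_bool(raw[name], i, name)
        kwargs["drugs"] = {d: _parse_bool(raw[d], i, d) for d in DRUG_FLAGS}
        try:
            records.append(PatientRecord(**kwargs))
        except InvalidInputError as exc:
            raise CohortSchemaError(f"row {i}: {exc}") from exc
    return Cohort(records=records, provenance="observed")


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV; the file round-trips through
    :func:`read_cohort_csv` losslessly."""
    cohort.to_dataframe().to_csv(path, index=False)
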