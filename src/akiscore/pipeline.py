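"""End-to-end study pipeline: validate the original score, update it with
the best candidate predictor, internally validate, and measure clinical
utility — all deterministic under a fixed seed."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import published
from .cohort import Cohort, read_cohort_csv, write_cohort_csv
from .errors import ConfigError
from .performance import (BootstrapConfig, PerformanceReport,
                          bootstrap_metrics, optimism_corrected_c)
from .score import (DEFAULT_WEIGHTS, ScoreModel, ScoreWeights, band_incidence,
                    coefficients_from_anchor, cohort_scores, score_record)
from .simulate import GeneratorConfig, generate_cohort
from .update import (assign_score_points, candidate_scan, recalibrate_extend)
from .utility import (bootstrap_nri_idi, decision_curve,
                      reclassification_table)

__all__ = ["RunConfig", "StudyReport", "run_full_analysis",
           "existing_score_model", "build_updated_model"]

logger = logging.getLogger(__name__)

DEFAULT_CANDIDATES = ("dxr", "mtx", "pem", "gem", "cpi", "vegf",
                      "capecitabine", "s1", "vp16", "no_mg", "sh")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``input_csv`` / ``generator`` selects the cohort source.
    """

    input_csv: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    seed: int = 0
    bootstrap_B: int = 10_000
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    score_cutpoints: tuple[float, float] = (4.0, 7.0)
    prob_cutpoints: tuple[float, float] = (0.10, 0.20)
    dca_grid: Optional[list[float]] = None
    optimism_B: int = 500
    out_dir: str = "akiscore_out"

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.generator is None):
            raise ConfigError(
                "exactly one of input_csv / generator must be given")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        gen = raw.pop("generator", None)
        if gen is not None:
            gen = GeneratorConfig(**gen)
        cands = raw.pop("candidates", None)
        kwargs: dict[str, Any] = dict(raw)
        if cands is not None:
            kwargs["candidates"] = tuple(cands)
        for key in ("score_cutpoints", "prob_cutpoints"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(generator=gen, **kwargs)

    def digest(self) -> str:
        def default(o: Any) -> Any:
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))
        text = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=default)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """All tables produced by one pipeline run, plus provenance."""

    univariate: pd.DataFrame
    candidate_scan: pd.DataFrame
    performance_existing: PerformanceReport
    performance_updated: PerformanceReport
    reclassification: pd.DataFrame
    nri: dict[str, Any]
    idi: dict[str, float]
    dca: pd.DataFrame
    band_incidence: dict[str, dict[str, Any]]
    optimism: dict[str, float]
    updated_model: ScoreModel
    existing_model: ScoreModel
    provenance: dict[str, Any]


def existing_score_model() -> ScoreModel:
    """The original published score with its reconstructed logistic anchor."""
    intercept, slope = coefficients_from_anchor(published.ANCHOR_P0,
                                                published.ANCHOR_OR_PER_POINT)
    return ScoreModel(weights=DEFAULT_WEIGHTS, intercept=intercept, slope=slope)


def build_updated_model(cohort: Cohort, extension_field: str,
                        ) -> tuple[ScoreModel, dict[str, float]]:
    """Recalibrate-and-extend on ``extension_field``, convert the fitted odds
    ratios to score points, and refit the anchor of the pointed score."""
    y = cohort.outcomes()
    base = cohort_scores(cohort, DEFAULT_WEIGHTS)
    extra = cohort.column(extension_field).astype(float)
    fit = recalibrate_extend(base, extra.reshape(-1, 1), y,
                             extra_names=(extension_field,))
    or_per_point = float(np.exp(fit.coefficients[1]))
    or_new = float(np.exp(fit.coefficients[2]))
    assignment = assign_score_points(or_new, or_per_point)
    weights = ScoreWeights(extensions={extension_field: assignment.points})
    updated = np.array([score_record(r, weights) for r in cohort])
    anchor = recalibrate_extend(updated, None, y)
    model = ScoreModel(weights=weights,
                       intercept=float(anchor.coefficients[0]),
                       slope=float(anchor.coefficients[1]))
    detail = {"or_new": or_new, "or_per_point": or_per_point,
              "raw_ratio": assignment.raw_ratio, "points": assignment.points,
              "intercept_or": float(np.exp(fit.coefficients[0]))}
    return model, detail


def _scan_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def _report_frame(report: PerformanceReport) -> pd.DataFrame:
    rows = [{"metric": m, "point": s.point, "boot_mean": s.boot_mean,
             "ci_low": s.ci_low, "ci_high": s.ci_high}
            for m, s in report.metrics.items()]
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig) -> StudyReport:
    """Run every stage in study order and write the tables to
    ``config.out_dir``; identical (config, seed) gives identical output."""
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str) -> None:
        logger.info("stage %-14s t=%.2fs", name, time.perf_counter() - t0)

    stage("cohort")
    if config.input_csv is not None:
        cohort = read_cohort_csv(config.input_csv)
    else:
        cohort, _ = generate_cohort(config.generator, config.seed)
        write_cohort_csv(cohort, out / "cohort.csv")
    y = cohort.outcomes()

    stage("univariate")
    from .univariate import univariate_table
    uni = univariate_table(cohort)
    _write_tsv(uni, out / "univariate.tsv", or_cols=("odds_ratio", "ci_low",
                                                     "ci_high"))

    stage("validate")
    existing = existing_score_model()
    boot = BootstrapConfig(B=config.bootstrap_B, seed=config.seed)
    perf_existing = bootstrap_metrics(cohort, existing, boot)

    stage("update")
    base = cohort_scores(cohort, DEFAULT_WEIGHTS)
    scan = candidate_scan(cohort, base, config.candidates)
    scan_df = _scan_frame(scan)
    _write_tsv(scan_df, out / "candidate_scan.tsv")
    winners = [r for r in scan if r.fitted and r.candidate != "None"
               and r.significant]
    if winners:
        chosen = winners[0].candidate  # rows already sorted by AIC
        model, detail = build_updated_model(cohort, chosen)
    else:
        logger.info("no candidate clears the AIC rule; pure recalibration")
        chosen = None
        anchor = recalibrate_extend(base, None, y)
        model = ScoreModel(weights=DEFAULT_WEIGHTS,
                           intercept=float(anchor.coefficients[0]),
                           slope=float(anchor.coefficients[1]))
        detail = {}
    model.to_json(out / "updated_model.json")
    existing.to_json(out / "existing_model.json")
    perf_updated = bootstrap_metrics(cohort, model, boot)
    _write_tsv(_report_frame(perf_existing), out / "performance_existing.tsv")
    _write_tsv(_report_frame(perf_updated), out / "performance_updated.tsv")

    stage("optimism")
    extension = chosen

    def builder(c: Cohort):
        yb = c.outcomes()
        sb = cohort_scores(c, DEFAULT_WEIGHTS)
        if extension is None:
            fit = recalibrate_extend(sb, None, yb)

            def predict(cc: Cohort) -> np.ndarray:
                s = cohort_scores(cc, DEFAULT_WEIGHTS)
                return fit.predict(s.reshape(-1, 1))
        else:
            xb = c.column(extension).astype(float)
            fit = recalibrate_extend(sb, xb.reshape(-1, 1), yb)

            def predict(cc: Cohort) -> np.ndarray:
                s = cohort_scores(cc, DEFAULT_WEIGHTS)
                x = cc.column(extension).astype(float)
                return fit.predict(np.column_stack([s, x]))
        return predict

    opt = optimism_corrected_c(
        cohort, builder, BootstrapConfig(B=config.optimism_B, seed=config.seed))

    stage("utility")
    from .score import predict_probability
    p_old = predict_probability(existing, base)
    updated_scores = np.array([score_record(r, model.weights) for r in cohort])
    p_new = predict_probability(model, updated_scores)
    reclass = reclassification_table(p_old, p_new, y, config.prob_cutpoints)
    nri_res, (idi_pt, idi_lo, idi_hi) = bootstrap_nri_idi(
        p_old, p_new, y, B=min(config.bootstrap_B, 2000), seed=config.seed,
        cutpoints=config.prob_cutpoints)
    dca = decision_curve({"existing": p_old, "updated": p_new}, y,
                         config.dca_grid)
    reclass_df = reclass.to_frame()
    _write_tsv(reclass_df, out / "reclassification.tsv")
    dca_df = dca.to_frame()
    dca_df.to_csv(out / "dca.csv", index=False)

    stage("bands")
    bands = band_incidence(cohort, lambda r: score_record(r, model.weights),
                           config.score_cutpoints)
    bands_df = pd.DataFrame([{"band": b, **v} for b, v in bands.items()])
    _write_tsv(bands_df, out / "band_incidence.tsv")

    from . import __version__
    provenance = {"seed": config.seed, "version": __version__,
                  "config_hash": config.digest(), "n": len(cohort),
                  "events": int(y.sum()), "chosen_extension": chosen,
                  **detail}
    nri_dict = dataclasses.asdict(nri_res)
    idi_dict = {"idi": idi_pt, "ci_low": idi_lo, "ci_high": idi_hi}
    report_json = {
        "provenance": provenance,
        "performance_existing": {m: dataclasses.asdict(s) for m, s in
                                 perf_existing.metrics.items()},
        "performance_updated": {m: dataclasses.asdict(s) for m, s in
                                perf_updated.metrics.items()},
        "optimism": dataclasses.asdict(opt),
        "nri": nri_dict,
        "idi": idi_dict,
        "band_incidence": bands,
    }
    (out / "report.json").write_text(json.dumps(report_json, indent=2))
    stage("done")

    return StudyReport(
        univariate=uni, candidate_scan=scan_df,
        performance_existing=perf_existing, performance_updated=perf_updated,
        reclassification=reclass_df, nri=nri_dict, idi=idi_dict,
        dca=dca_df, band_incidence=bands,
        optimism=dataclasses.asdict(opt), updated_model=model,
        existing_model=existing, provenance=provenance)


def _write_tsv(df: pd.DataFrame, path: Path,
               or_cols: tuple[str, ...] = ()) -> None:
    """Fixed formatting: 2 decimals for odds-ratio columns, 3 elsewhere."""
    df = df.copy()
    for col in df.columns:
        if df[col].dtype.kind == "f":
            nd = 2 if col in or_cols else 3
            df[col] = df[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.{nd}f}")
    df.to_csv(path, sep="\t", index=False)
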