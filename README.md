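# akiscore

Tools for validating and updating a points-based clinical risk score for
cisplatin-induced acute kidney injury (AKI). The package implements the full
study pipeline around such a score:

- **Cohort model** (`akiscore.cohort`) — patient records, strict CSV I/O,
  outcome classification (≥0.3 mg/dL creatinine rise within 14 days, with
  AKIN-style severity staging), Cockcroft–Gault creatinine clearance, the
  2009 CKD-EPI eGFR equation, short-hydration and CKD flags.
- **Synthetic cohorts** (`akiscore.simulate`) — seeded generators whose
  covariate marginals match the published cohort table and whose outcomes
  are drawn from a logistic model on the risk score plus a no-magnesium
  term; follow-up creatinine is constructed so that outcome classification
  reproduces the drawn label exactly.
- **Risk score** (`akiscore.score`) — the four-factor points table
  (age / albumin / cisplatin dose / hypertension, 0–9.5 points), the
  no-magnesium extension (+3.0 points, max 12.5), the logistic anchor
  mapping score to probability, and score/probability risk bands.
- **Univariate screening** (`akiscore.univariate`) — 2×2 odds ratios with
  Woolf intervals, Fisher's exact test, Mann–Whitney U, per-unit logistic
  odds ratios.
- **Model updating** (`akiscore.update`) — a monotone Newton logistic
  fitter, recalibration-and-extension (the original score enters as a
  single predictor and its internal weights are never refit), one-at-a-time
  candidate scanning with the ΔAIC > 10 rule, odds-ratio-division score
  point assignment, VIF screening.
- **Performance evaluation** (`akiscore.performance`) — Cox–Snell and
  Nagelkerke R², Brier score, calibration-in-the-large, calibration slope,
  O/E ratio, integrated calibration index, C-statistic; percentile
  bootstrap CIs and bootstrap optimism correction of the C-statistic.
- **Clinical utility** (`akiscore.utility`) — categorical NRI from paired
  3×3 reclassification tables, IDI, and decision curve analysis.
- **Pipeline** (`akiscore.pipeline`, `akiscore.cli`) — one reproducible
  end-to-end run with per-stage outputs.

## Command line

```sh
# draw a 1785-patient synthetic cohort (writes CSV + provenance sidecar)
akiscore simulate --n 1785 --seed 1 --out cohort.csv

# univariate screening table
akiscore univariate cohort.csv --out univariate.tsv

# metric battery for the published score (fixed anchor, no refit)
akiscore validate cohort.csv --bootstrap 2000 --seed 1 --out performance.tsv

# candidate scan + recalibration-and-extension update
akiscore update cohort.csv --out-dir update/

# reclassification, NRI/IDI, decision curves for two models
akiscore utility cohort.csv --old-model existing.json \
    --new-model update/updated_model.json --out-dir utility/

# everything in study order from one config
akiscore run-all --config examples/run.yaml --seed 7
```

`run-all` writes `cohort.csv`, `univariate.tsv`, `candidate_scan.tsv`,
`performance_{existing,updated}.tsv`, `reclassification.tsv`,
`dca.csv`, `band_incidence.tsv`, both model JSONs, and a `report.json`
with full-precision numbers and provenance (seed, version, config hash).
Logs go to stderr; exit codes are 0 (success), 1 (runtime error),
2 (usage error).

## Library example

```python
from akiscore import GeneratorConfig, generate_cohort
from akiscore.score import DEFAULT_WEIGHTS, cohort_scores
from akiscore.update import candidate_scan, recalibrate_extend

cohort, p_true = generate_cohort(GeneratorConfig(n=1785), seed=7)
score = cohort_scores(cohort, DEFAULT_WEIGHTS)
rows = candidate_scan(cohort, score, ["no_mg", "gem", "sh"])
fit = recalibrate_extend(score, cohort.column("no_mg").astype(float),
                         cohort.outcomes())
```
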