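"""Published summary data from the source single-centre cohort study.

These constants are the printed inputs the package can reproduce without the
(restricted) patient-level data: 2x2 outcome-by-exposure counts, the paired
3x3 reclassification tables, the published logistic anchor of the original
score, and the fitted odds ratios used for point assignment.
"""

from __future__ import annotations

N_TOTAL = 1785
N_EVENTS = 205
N_NONEVENTS = 1580

#: (event_exposed, event_unexposed, nonevent_exposed, nonevent_unexposed)
#: per exposure, as printed in the univariate table.
TWO_BY_TWO_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "no_mg": (88, 117, 264, 1316),
    "male": (166, 39, 1065, 515),
    "gem": (48, 157, 134, 1446),
    "hypertension": (107, 98, 556, 1024),
    "capecitabine": (2, 203, 2, 1578),
    "sh": (29, 176, 343, 1237),
    "mtx": (4, 201, 3, 1577),
    "s1": (23, 182, 98, 1482),
    "vp16": (11, 194, 44, 1536),
    "diabetes": (33, 172, 201, 1379),
}

#: Paired 3x3 reclassification counts, rows = original-model band
#: (low/intermediate/high), columns = updated-model band.
RECLASS_EVENTS: list[list[int]] = [[30, 26, 0], [27, 43, 20], [0, 28, 31]]
RECLASS_NONEVENTS: list[list[int]] = [[623, 74, 0], [243, 322, 63], [0, 189, 66]]

#: Anchor of the original published score: outcome probability 0.04 at
#: score 0 and odds ratio 1.49 per score point.
ANCHOR_P0 = 0.04
ANCHOR_OR_PER_POINT = 1.49

#: Fitted odds ratios from the recalibration-and-extension model.
OR_NO_MG = 3.91
OR_PER_POINT = 1.29

#: Marginal prevalences used by the synthetic-cohort defaults.
PREVALENCE = {
    "male": 0.690,
    "hypertension": 0.371,
    "diabetes": 0.131,
    "no_mg": 0.197,
    "sh": 0.208,
}

#: Drug-exposure prevalences from the univariate table.
DRUG_PREVALENCE = {
    "capecitabine": 0.002,
    "cpa": 0.004,
    "cpt11": 0.040,
    "dtx": 0.336,
    "dxr": 0.068,
    "gem": 0.102,
    "mtx": 0.004,
    "pem": 0.056,
    "ptx": 0.040,
    "s1": 0.068,
    "vnr": 0.036,
    "vp16": 0.031,
    "fu5": 0.397,
    "egfri": 0.003,
    "vegf": 0.031,
    "cpi": 0.012,
}

#: Median and interquartile range of the continuous covariates.
CONTINUOUS_DISTS = {
    "age": (66.0, 59.0, 71.0),
    "weight_kg": (57.6, 50.1, 65.5),
    "albumin_gdl": (3.9, 3.5, 4.2),
    "cddp_dose_mg": (110.0, 90.0, 128.0),
    "scr_baseline": (0.7, 0.6, 0.9),
}
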