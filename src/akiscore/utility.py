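"""Reclassification metrics (categorical NRI, IDI) and decision curve
analysis for comparing an updated risk model against the original."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .score import BANDS, probability_band

__all__ = [
    "ReclassTable",
    "NriResult",
    "DcaCurve",
    "reclassification_table",
    "nri_from_table",
    "idi",
    "net_benefit",
    "decision_curve",
    "bootstrap_nri_idi",
]


@dataclass(frozen=True)
class ReclassTable:
    """Paired 3x3 cross-tabulations of old-vs-new risk categories.

    Rows index the old category, columns the new, both ordered
    low/intermediate/high; events and non-events are tabulated separately.
    """

    events: np.ndarray
    nonevents: np.ndarray

    def __post_init__(self) -> None:
        ev = np.asarray(self.events, dtype=int)
        ne = np.asarray(self.nonevents, dtype=int)
        if ev.shape != (3, 3) or ne.shape != (3, 3):
            raise InvalidInputError("tables must be 3x3")
        if (ev < 0).any() or (ne < 0).any():
            raise InvalidInputError("counts must be non-negative")
        object.__setattr__(self, "events", ev)
        object.__setattr__(self, "nonevents", ne)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def n_nonevents(self) -> int:
        return int(self.nonevents.sum())

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for label, tbl in (("event", self.events), ("nonevent", self.nonevents)):
            df = pd.DataFrame(tbl, index=BANDS, columns=BANDS)
            df.insert(0, "group", label)
            df.insert(1, "old_band", BANDS)
            frames.append(df.reset_index(drop=True))
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class NriResult:
    """Categorical net reclassification improvement and its components."""

    up_events: int
    down_events: int
    up_nonevents: int
    down_nonevents: int
    nri_events: float
    nri_nonevents: float
    nri: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


@dataclass(frozen=True)
class DcaCurve:
    """Net-benefit curves over a threshold grid, as a tidy table."""

    thresholds: np.ndarray
    curves: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"threshold": self.thresholds})
        for name, nb in self.curves.items():
            df[name] = nb
        return df


def reclassification_table(p_old: Sequence[float], p_new: Sequence[float],
                           y: Sequence[int],
                           cutpoints: tuple[float, float] = (0.10, 0.20),
                           ) -> ReclassTable:
    """Cross-tabulate each patient's old and new probability band, split by
    outcome."""
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    y = np.asarray(y, dtype=int)
    if not (p_old.size == p_new.size == y.size):
        raise InvalidInputError("inputs must share a length")
    band_index = {b: i for i, b in enumerate(BANDS)}
    ev = np.zeros((3, 3), dtype=int)
    ne = np.zeros((3, 3), dtype=int)
    for po, pn, yi in zip(p_old, p_new, y):
        i = band_index[probability_band(po, cutpoints)]
        j = band_index[probability_band(pn, cutpoints)]
        (ev if yi else ne)[i, j] += 1
    return ReclassTable(events=ev, nonevents=ne)


def nri_from_table(t: ReclassTable) -> NriResult:
    """NRI from the paired tables: upward moves are favourable for events,
    downward moves for non-events."""
    upper = np.triu(np.ones((3, 3), dtype=bool), k=1)
    lower = np.tril(np.ones((3, 3), dtype=bool), k=-1)
    up_ev = int(t.events[upper].sum())
    down_ev = int(t.events[lower].sum())
    up_ne = int(t.nonevents[upper].sum())
    down_ne = int(t.nonevents[lower].sum())
    if t.n_events == 0 or t.n_nonevents == 0:
        raise InvalidInputError("both outcome groups must be non-empty")
    nri_ev = (up_ev - down_ev) / t.n_events
    nri_ne = (down_ne - up_ne) / t.n_nonevents
    return NriResult(up_events=up_ev, down_events=down_ev, up_nonevents=up_ne,
                     down_nonevents=down_ne, nri_events=nri_ev,
                     nri_nonevents=nri_ne, nri=nri_ev + nri_ne)


def idi(p_old: Sequence[float], p_new: Sequence[float],
        y: Sequence[int]) -> float:
    """Integrated discrimination improvement: gain in the mean predicted
    risk separation between events and non-events."""
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    y = np.asarray(y, dtype=int)
    if not (p_old.size == p_new.size == y.size):
        raise InvalidInputError("inputs must share a length")
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise InvalidInputError("both outcome classes must be present")
    ev, ne = y == 1, y == 0
    return float((p_new[ev].mean() - p_old[ev].mean())
                 - (p_new[ne].mean() - p_old[ne].mean()))


def net_benefit(p: Sequence[float], y: Sequence[int], pt: float) -> float:
    """True-positive rate minus threshold-odds-weighted false-positive rate,
    treating a patient whenever the predicted probability is >= ``pt``."""
    if not 0.0 < pt < 1.0:
        raise InvalidInputError("threshold must lie strictly in (0, 1)")
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=int)
    n = y.size
    treated = p >= pt
    tp = int(np.sum(treated & (y == 1)))
    fp = int(np.sum(treated & (y == 0)))
    return tp / n - (fp / n) * pt / (1.0 - pt)


def decision_curve(p_models: dict[str, Sequence[float]], y: Sequence[int],
                   grid: Optional[Sequence[float]] = None) -> DcaCurve:
    """Net benefit per model across a threshold grid, plus treat-all and
    treat-none reference curves."""
    y = np.asarray(y, dtype=int)
    if grid is None:
        grid = np.arange(0.01, 0.9901, 0.005)
    grid = np.asarray(grid, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise InvalidInputError("grid thresholds must lie strictly in (0, 1)")
    curves: dict[str, np.ndarray] = {}
    for name, p in p_models.items():
        p = np.asarray(p, dtype=float)
        curves[f"nb_{name}"] = np.array([net_benefit(p, y, t) for t in grid])
    ones = np.ones(y.size)
    curves["nb_treat_all"] = np.array([net_benefit(ones, y, t) for t in grid])
    curves["nb_treat_none"] = np.zeros(grid.size)
    return DcaCurve(thresholds=grid, curves=curves)


def bootstrap_nri_idi(p_old: Sequence[float], p_new: Sequence[float],
                      y: Sequence[int], B: int = 2000, seed: int = 0,
                      ci: float = 0.95,
                      cutpoints: tuple[float, float] = (0.10, 0.20),
                      ) -> tuple[NriResult, tuple[float, float, float]]:
    """Patient-level bootstrap CIs for NRI and IDI.

    Returns the NRI result with its interval attached, and
    ``(idi_point, idi_lo, idi_hi)``.
    """
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    y = np.asarray(y, dtype=int)
    point = nri_from_table(reclassification_table(p_old, p_new, y, cutpoints))
    idi_point = idi(p_old, p_new, y)
    rng = np.random.default_rng(seed)
    n = y.size
    nris, idis = [], []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        nris.append(nri_from_table(
            reclassification_table(p_old[idx], p_new[idx], yb, cutpoints)).nri)
        idis.append(idi(p_old[idx], p_new[idx], yb))
    alpha = 1.0 - ci
    qs = [alpha / 2.0, 1.0 - alpha / 2.0]
    nri_lo, nri_hi = np.quantile(nris, qs)
    idi_lo, idi_hi = np.quantile(idis, qs)
    full = NriResult(**{**point.__dict__, "ci_low": float(nri_lo),
                        "ci_high": float(nri_hi)})
    return full, (idi_point, float(idi_lo), float(idi_hi))
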