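"""Derived egg-laying traits per stage and the 3-sigma outlier filter.

Thirteen traits are computed per laying stage from daily 0/1 records:
five production traits (EV, WMLR, WEV, BWMLR, BWEV), three clutch traits
(CPN, TCS, ECI) and five interval traits (LIT, AILI, TILI, MILI, II).
A clutch is a maximal run of consecutive laying days; ECI and II are
restricted to "effective" clutches of length >= 2:

    ECI = TCS_{c>=2} / CPN_{c>=2}        II = (number of intervals) / CPN_{c>=2}

Intervals are maximal runs of non-laying days strictly between the
stage's first and last egg; zeros before onset or after the last egg
reflect maturity, not laying gaps, and are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import StageDefinition
from .simdata import LayingRecords, week_day_slice

STAGE_NAMES = ("up", "sustained", "all")
TRAIT_NAMES = ("EV", "WMLR", "WEV", "BWMLR", "BWEV",
               "CPN", "TCS", "ECI",
               "LIT", "AILI", "TILI", "MILI", "II")

#: Desirable direction per trait: +1 higher-is-better, -1 lower-is-better.
#: Drives BHA/UHA polarity downstream. Interval traits and variance traits
#: are lower-is-better; intensity/rate/clutch-size traits higher-is-better.
TRAIT_DIRECTION = {
    "EV": -1, "WMLR": +1, "WEV": -1, "BWMLR": +1, "BWEV": -1,
    "CPN": -1, "TCS": +1, "ECI": +1,
    "LIT": +1, "AILI": -1, "TILI": -1, "MILI": -1, "II": -1,
}


@dataclass
class ClutchStructure:
    clutches: list[int]  # lengths of maximal runs of 1s
    intervals: list[int]  # lengths of 0-runs strictly between first/last egg
    stage_days: int

    @property
    def effective_clutches(self) -> list[int]:
        return [c for c in self.clutches if c >= 2]


def detect_clutches(day_vector) -> ClutchStructure:
    """Decompose one stage's daily 0/1 vector into clutches and intervals."""
    v = np.asarray(day_vector, dtype=np.int8)
    if v.size and not np.isin(v, (0, 1)).all():
        raise ValueError("day vector must be binary")
    ones = np.flatnonzero(v)
    if ones.size == 0:
        return ClutchStructure([], [], len(v))
    core = v[ones[0]: ones[-1] + 1]
    # run-length encode the core (starts and ends with 1)
    change = np.flatnonzero(np.diff(core)) + 1
    bounds = np.concatenate([[0], change, [len(core)]])
    lengths = np.diff(bounds)
    values = core[bounds[:-1]]
    clutches = lengths[values == 1].tolist()
    intervals = lengths[values == 0].tolist()
    return ClutchStructure([int(c) for c in clutches],
                           [int(i) for i in intervals], len(v))


def _stage_day_index(stage_weeks: np.ndarray) -> np.ndarray:
    return np.concatenate([np.r_[week_day_slice(int(w))] for w in stage_weeks])


def _row_traits(v: np.ndarray, n_weeks: int) -> dict:
    weekly = v.reshape(n_weeks, 7).sum(axis=1)
    out = {}
    out["EV"] = float(np.var(weekly, ddof=1)) if n_weeks > 1 else np.nan
    out["WMLR"] = float(weekly.max()) / 7.0
    out["WEV"] = float(np.var(weekly / 7.0, ddof=1)) if n_weeks > 1 else np.nan
    if n_weeks >= 2:
        nbw = n_weeks // 2
        biweekly = weekly[: 2 * nbw].reshape(nbw, 2).sum(axis=1)
        out["BWMLR"] = float(biweekly.max()) / 14.0
        out["BWEV"] = float(np.var(biweekly / 14.0, ddof=1)) if nbw > 1 else np.nan
    else:
        out["BWMLR"] = np.nan
        out["BWEV"] = np.nan
    cs = detect_clutches(v)
    out["CPN"] = float(len(cs.clutches))
    out["TCS"] = float(sum(cs.clutches))
    eff = cs.effective_clutches
    out["ECI"] = float(sum(eff)) / len(eff) if eff else np.nan
    out["II"] = float(len(cs.intervals)) / len(eff) if eff else np.nan
    ones = np.flatnonzero(v)
    out["LIT"] = float(ones[-1] - ones[0] + 1) if ones.size else 0.0
    out["TILI"] = float(sum(cs.intervals))
    out["MILI"] = float(max(cs.intervals)) if cs.intervals else 0.0
    out["AILI"] = out["TILI"] / len(cs.intervals) if cs.intervals else 0.0
    return out


def derive_traits(records: LayingRecords, stages: StageDefinition) -> pd.DataFrame:
    """13 derived traits x 3 stages; columns '<stage>-<TRAIT>' (e.g. 'up-ECI')."""
    cols = {}
    for stage in STAGE_NAMES:
        weeks = stages.weeks(stage)
        if len(weeks) * 7 < 14:
            warnings.warn(f"stage {stage} shorter than 14 days: bi-weekly traits missing")
        days = _stage_day_index(weeks)
        sub = records.matrix[:, days]
        rows = [_row_traits(sub[i], len(weeks)) for i in range(sub.shape[0])]
        for t in TRAIT_NAMES:
            cols[f"{stage}-{t}"] = [r[t] for r in rows]
    return pd.DataFrame(cols, index=pd.Index(records.samples, name="sample"))


def remove_outliers_3sigma(table: pd.DataFrame) -> pd.DataFrame:
    """Single-pass per-column 3-sigma filter: values outside mean +/- 3 SD -> NaN."""
    out = table.copy()
    for col in out.columns:
        x = out[col]
        m, s = x.mean(), x.std(ddof=1)
        if not np.isfinite(s) or s == 0:
            continue
        out.loc[(x - m).abs() > 3 * s, col] = np.nan
    return out


def mean_fill(table: pd.DataFrame) -> pd.DataFrame:
    """Column-mean fill of missing trait values (convenience utility only)."""
    return table.fillna(table.mean())


def weekly_mean_rates(records: LayingRecords) -> np.ndarray:
    """Cohort mean laying rate per week of age (input to curve fitting)."""
    n_weeks = records.matrix.shape[1] // 7
    weekly = records.matrix.reshape(records.matrix.shape[0], n_weeks, 7).mean(axis=2)
    return weekly.mean(axis=0)
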