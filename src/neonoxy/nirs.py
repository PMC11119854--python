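"""Regional NIRS processing: fractional oxygen extraction, baseline deltas,
risk flagging and SaO2-range binning.

Regional tissue saturation (rSO2, percent) from near-infrared spectroscopy
is venous-weighted; fractional oxygen extraction is the share of delivered
arterial oxygen removed by tissue,

    FOE = (SaO2 - rSO2) / SaO2,

computable from the NIRS reading or from a co-drawn regional venous blood
gas (SvO2 in place of rSO2). Because inter-animal baseline variability is
large, per-animal deltas from baseline carry the signal; two risk flags are
used for the brain: an absolute cerebral saturation below 45% and a
relative drop of more than 20% from baseline.
"""
from __future__ import annotations

import logging
import math
import warnings
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats

from .errors import DomainError, InsufficientDataError, SchemaError

__all__ = [
    "NIRSSite",
    "NIRSReading",
    "FOEResult",
    "RiskFlags",
    "SAO2_BIN_LABELS",
    "foe_from_nirs",
    "foe_from_gases",
    "delta_from_baseline",
    "flag_risk",
    "assign_sao2_bin",
    "bin_by_sao2",
    "pooled_flagged_fraction",
    "fit_linear_trend",
    "round_half_up_percent",
]

logger = logging.getLogger(__name__)


class NIRSSite(str, Enum):
    brain = "brain"
    gut = "gut"
    kidney = "kidney"


class NIRSReading(BaseModel):
    """One regional saturation reading (percent scale)."""

    site: NIRSSite
    rSO2: float = Field(ge=0, le=100)
    period: str
    animal_id: str


class FOEResult(BaseModel):
    site: NIRSSite
    period: str
    foe: float = Field(ge=-1, le=1)
    source: str = "nirs"  # or "blood_gas"
    delta_from_baseline: Optional[float] = None


class RiskFlags(BaseModel):
    """Cerebral-risk flags for one reading against its baseline."""

    below_45: bool
    drop_gt20: bool
    relative_drop: float


#: SaO2 bin labels, percent scale, half-open [lower, upper) with the top
#: bin closed at 100.
SAO2_BIN_LABELS = ("95-100", "90-95", "85-90", "<85")
_SAO2_BIN_EDGES = (95.0, 90.0, 85.0)


def _check_fraction(name: str, value: np.ndarray, lo=0.0, hi=1.0):
    if np.any(value < lo) or np.any(value > hi):
        raise DomainError(f"{name} must lie in [{lo}, {hi}]")


def foe_from_nirs(sao2, rso2):
    """Fractional oxygen extraction from arterial and NIRS saturations.

    Both arguments are fractions in [0, 1]; ``sao2`` must be positive.
    """
    s = np.asarray(sao2, dtype=float)
    r = np.asarray(rso2, dtype=float)
    if np.any(s <= 0):
        raise DomainError("sao2 must be strictly positive")
    _check_fraction("sao2", s)
    _check_fraction("rso2", r)
    out = (s - r) / s
    return float(out) if np.ndim(sao2) == 0 and np.ndim(rso2) == 0 else out


def foe_from_gases(sao2, svo2):
    """FOE from arterial and regional venous blood-gas saturations."""
    return foe_from_nirs(sao2, svo2)


def delta_from_baseline(
    series: pd.DataFrame,
    value_col: str = "value",
    baseline_period: str = "baseline",
) -> pd.DataFrame:
    """Per-animal, per-site absolute and relative deltas from baseline.

    ``series`` needs columns ``animal_id``, ``site``, ``period`` and the
    value column. Returns a copy with ``delta_abs`` and ``delta_rel``
    (``(value - baseline) / baseline``); the baseline rows carry 0.
    """
    required = {"animal_id", "site", "period", value_col}
    missing = required - set(series.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    out = series.copy()
    out["delta_abs"] = np.nan
    out["delta_rel"] = np.nan
    for (animal, site), grp in out.groupby(["animal_id", "site"], sort=False):
        base_rows = grp[grp["period"] == baseline_period]
        if base_rows.empty:
            raise DomainError(
                f"no baseline period for animal {animal!r}, site {site!r}"
            )
        base = float(base_rows[value_col].iloc[0])
        out.loc[grp.index, "delta_abs"] = grp[value_col] - base
        out.loc[grp.index, "delta_rel"] = (grp[value_col] - base) / base
    return out


def flag_risk(rso2: float, baseline: float) -> RiskFlags:
    """Risk flags for a cerebral saturation reading (percent scale).

    Both thresholds use strict inequalities: exactly 45% or exactly a 20%
    drop is not flagged.
    """
    for name, v in (("rso2", rso2), ("baseline", baseline)):
        if not 0 <= v <= 100:
            raise DomainError(f"{name} must lie in [0, 100] percent")
    if baseline <= 0:
        raise DomainError("baseline must be strictly positive")
    relative_drop = (baseline - rso2) / baseline
    return RiskFlags(
        below_45=bool(rso2 < 45.0),
        drop_gt20=bool(relative_drop > 0.20),
        relative_drop=float(relative_drop),
    )


def assign_sao2_bin(sao2_percent: float) -> str:
    """Assign an SaO2 value (percent) to its range label.

    Half-open convention [lower, upper), top bin closed at 100: a value of
    exactly 95.0 belongs to "95-100".
    """
    if not 0 <= sao2_percent <= 100:
        raise DomainError("sao2 must lie in [0, 100] percent")
    for label, edge in zip(SAO2_BIN_LABELS, _SAO2_BIN_EDGES):
        if sao2_percent >= edge:
            return label
    return SAO2_BIN_LABELS[-1]


def round_half_up_percent(fraction: float) -> int:
    """Integer percent with half-up rounding (0.635 -> 64)."""
    return int(math.floor(fraction * 100.0 + 0.5))


def bin_by_sao2(observations: pd.DataFrame) -> pd.DataFrame:
    """Table of rcSO2 statistics and risk counts by SaO2 range and group.

    ``observations`` holds post-injury/sham rows with columns ``sao2``
    (percent, or fraction which is converted), ``rcso2`` (percent),
    ``group`` (``control``/``oa``) and ``baseline`` (percent, the animal's
    baseline rcSO2). Returns one row per SaO2 range with per-group N,
    mean (SE) rcSO2, and the count and rounded percent of readings with a
    >20% relative drop from baseline. Empty cells report N = 0 and null
    statistics.
    """
    required = {"sao2", "rcso2", "group", "baseline"}
    missing = required - set(observations.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    obs = observations.copy()
    sao2 = np.asarray(obs["sao2"], dtype=float)
    if np.all(sao2 <= 1.0):  # fraction scale
        sao2 = sao2 * 100.0
    obs["sao2_pct"] = sao2
    obs["bin"] = [assign_sao2_bin(v) for v in sao2]
    obs["drop_gt20"] = [
        flag_risk(r, b).drop_gt20
        for r, b in zip(obs["rcso2"], obs["baseline"])
    ]

    rows = []
    for label in SAO2_BIN_LABELS:
        row = {"range": label}
        for group, tag in (("control", "control"), ("oa", "oa")):
            sub = obs[(obs["bin"] == label) & (obs["group"] == group)]
            n = len(sub)
            row[f"n_{tag}"] = n
            if n:
                row[f"mean_{tag}"] = float(sub["rcso2"].mean())
                row[f"se_{tag}"] = (
                    float(sub["rcso2"].std(ddof=1) / math.sqrt(n))
                    if n > 1
                    else 0.0
                )
                flagged = int(sub["drop_gt20"].sum())
                row[f"flagged_{tag}"] = flagged
                row[f"flagged_pct_{tag}"] = round_half_up_percent(flagged / n)
            else:
                row[f"mean_{tag}"] = np.nan
                row[f"se_{tag}"] = np.nan
                row[f"flagged_{tag}"] = 0
                row[f"flagged_pct_{tag}"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("range")
    assert int(table[["n_control", "n_oa"]].to_numpy().sum()) == len(obs)
    return table


def pooled_flagged_fraction(
    observations: pd.DataFrame,
    group: str = "oa",
    min_sao2: float = 90.0,
) -> tuple[int, int, int]:
    """Flagged count, N and rounded percent pooled over SaO2 >= ``min_sao2``.

    Reproduces summaries of the form "11/16 measurements (69%)" for
    readings above an arterial-saturation threshold.
    """
    obs = observations.copy()
    sao2 = np.asarray(obs["sao2"], dtype=float)
    if np.all(sao2 <= 1.0):
        sao2 = sao2 * 100.0
    mask = (obs["group"] == group) & (sao2 >= min_sao2)
    sub = obs[mask]
    n = len(sub)
    if n == 0:
        return 0, 0, 0
    flagged = int(
        sum(
            flag_risk(r, b).drop_gt20
            for r, b in zip(sub["rcso2"], sub["baseline"])
        )
    )
    return flagged, n, round_half_up_percent(flagged / n)


def fit_linear_trend(x: Sequence[float], y: Sequence[float]):
    """Ordinary least-squares line: returns ``(slope, intercept, r_squared)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise InsufficientDataError("at least 3 points required for a trend")
    if x.size != y.size:
        raise DomainError("x and y must have equal length")
    if np.ptp(x) == 0:
        raise DomainError("all x values identical: degenerate design")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
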