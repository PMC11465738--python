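"""Thermal and alkali stability analytics: WA units, residuals, half-life.

Activity in the indicator assay is expressed in Wilbur-Anderson (WA) units,
(t_uncatalyzed - t_catalyzed) / t_catalyzed, from the time the indicator
needs to traverse a fixed pH drop with and without enzyme. Residual activity
or solubility after an incubation is the percentage of the t = 0 value;
values above 100% are permitted (thermal activation). The half-life is read
off the decay series by log-linear interpolation, i.e. assuming first-order
decay between samples, after discarding any transient activation bump by
starting at the series maximum.

The WA-unit and residual formulas are the classical reconstructions of the
assay conventions and are labeled as such in outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "DecaySeries",
    "StabilityResult",
    "wa_units",
    "residual_fraction",
    "half_life",
    "read_decay_csv",
]

FORMULA_PROVENANCE = "reconstructed-formula: classical Wilbur-Anderson conventions"


@dataclass(frozen=True)
class DecaySeries:
    """Residual activity/solubility (%) at incubation times (hours)."""

    timepoints: np.ndarray
    residual: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        r = np.asarray(self.residual, dtype=float)
        object.__setattr__(self, "timepoints", t)
        object.__setattr__(self, "residual", r)
        if t.size < 2:
            raise ValueError("decay series needs at least 2 points")
        if t.size != r.size:
            raise ValueError("timepoints and residuals differ in length")
        if t[0] != 0:
            raise ValueError("first timepoint must be 0")
        if not np.all(np.diff(t) > 0):
            raise ValueError("timepoints must be strictly increasing")
        # the t = 0 point is the normalization reference; allow generous
        # instrument noise around 100%
        if abs(r[0] - 100.0) > 30.0:
            raise ValueError("residual at t = 0 must be 100% within noise tolerance")


@dataclass(frozen=True)
class StabilityResult:
    half_life: Optional[float]  # hours; None when the series never crosses 50%
    residuals: DecaySeries
    condition: str
    provenance: str = FORMULA_PROVENANCE

    def __post_init__(self) -> None:
        if self.half_life is not None and not self.half_life > 0:
            raise ValueError("half-life must be positive when defined")


def wa_units(t_uncatalyzed: float, t_catalyzed: float) -> float:
    """Wilbur-Anderson activity units: (t0 - t) / t.

    ``t_uncatalyzed`` and ``t_catalyzed`` are the times (s) for the indicator
    to traverse the assay pH drop without and with enzyme.
    """
    if t_catalyzed <= 0:
        raise ValueError("catalyzed time must be positive")
    if t_uncatalyzed <= 0:
        raise ValueError("uncatalyzed time must be positive")
    return (t_uncatalyzed - t_catalyzed) / t_catalyzed


def residual_fraction(value_t: float, value_0: float) -> float:
    """Residual percentage 100 * value_t / value_0; may exceed 100%."""
    if value_0 <= 0:
        raise ValueError("reference value must be positive")
    if value_t < 0:
        raise ValueError("measurement must be non-negative")
    return 100.0 * value_t / value_0


def half_life(series: DecaySeries) -> Optional[float]:
    """First 50%-crossing time by log-linear interpolation, or None.

    The series is restricted to the maximal suffix starting at its maximum so
    that a transient thermal-activation rise does not enter the decay. If a
    sample sits exactly at 50% its time is returned; otherwise the crossing
    is interpolated on log-residual between the bracketing points. Returns
    None when the series never reaches 50% (that is a value, not an error).
    """
    t = series.timepoints
    r = series.residual
    start = int(np.argmax(r))
    t, r = t[start:], r[start:]
    for i in range(len(r)):
        if r[i] == 50.0:
            return float(t[i])
        if r[i] < 50.0:
            if i == 0:
                return None  # already below 50% at the maximum: undefined decay
            r1, r2 = r[i - 1], r[i]
            t1, t2 = t[i - 1], t[i]
            if r2 <= 0:
                # log interpolation undefined; fall back to linear crossing
                return float(t1 + (t2 - t1) * (r1 - 50.0) / (r1 - r2))
            return float(t1 + (t2 - t1) * math.log(r1 / 50.0) / math.log(r1 / r2))
    return None


def read_decay_csv(path) -> DecaySeries:
    """Read a decay series from CSV.

    Accepts columns (time_h, residual_pct) or (time_h, raw_value); raw values
    are normalized so that t = 0 reads 100%.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "time_h" not in cols:
        raise ValueError("decay CSV needs a time_h column")
    t = df[cols["time_h"]].to_numpy(dtype=float)
    if "residual_pct" in cols:
        r = df[cols["residual_pct"]].to_numpy(dtype=float)
    elif "raw_value" in cols:
        raw = df[cols["raw_value"]].to_numpy(dtype=float)
        order = np.argsort(t)
        t0_val = raw[order[0]]
        if t0_val <= 0:
            raise ValueError("raw value at t = 0 must be positive")
        r = 100.0 * raw / t0_val
    else:
        raise ValueError("decay CSV needs residual_pct or raw_value column")
    order = np.argsort(t)
    return DecaySeries(timepoints=t[order], residual=r[order])


def analyze(series: DecaySeries, condition: str = "") -> StabilityResult:
    return StabilityResult(half_life=half_life(series), residuals=series, condition=condition)
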