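"""Specific-growth-rate estimation from biomass time courses.

The specific growth rate mu is the log-slope of biomass during the
exponential phase, mu = d ln X / dt.  Because "exponential phase" is a
judgement call on real curves, the estimator makes it reproducible: it
scans every contiguous window of at least ``min_window`` usable points,
fits ln X against t by ordinary least squares in each, and returns the
slope of the window with the highest R^2 (ties broken by longer window,
then earlier start).  Points at or below the detection floor are excluded
before windowing and are never log-transformed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError

__all__ = ["TimeSeries", "GrowthRateEstimate", "estimate_mu", "estimate_mu_replicates"]

Quantity = Literal["biomass", "crvi", "glucose"]

#: resolution at which window R^2 values are considered tied
_R2_TIE_DECIMALS = 12


@dataclass(frozen=True)
class TimeSeries:
    """One measured quantity over time for one condition/replicate.

    times in hours (strictly increasing); values in OD600 for biomass and
    mg/L for concentrations.
    """

    times: tuple[float, ...]
    values: tuple[float, ...]
    quantity: Quantity
    replicate_id: str = "rep1"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size:
            raise DomainError("times and values must have equal length")
        if t.size < 2:
            raise DomainError("a time series needs at least 2 points")
        if np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(v < 0):
            raise DomainError("values must be >= 0")
        if self.quantity not in ("biomass", "crvi", "glucose"):
            raise DomainError(f"unknown quantity {self.quantity!r}")
        # normalise to tuples so the dataclass stays hashable/frozen
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    def __len__(self) -> int:
        return len(self.times)

    def t_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    def v_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class GrowthRateEstimate:
    """Log-slope growth-rate estimate with the window that produced it."""

    mu: float
    window_start: float
    window_end: float
    r_squared: float
    n_points: int

    def __post_init__(self):
        if not self.window_start < self.window_end:
            raise DomainError("window_start must precede window_end")
        if self.n_points < 3:
            raise DomainError("a growth-rate window needs >= 3 points")
        if not 0.0 <= self.r_squared <= 1.0:
            raise DomainError("r_squared must lie in [0, 1]")


def _log_linear_fit(t: np.ndarray, ln_x: np.ndarray) -> tuple[float, float]:
    """OLS slope and R^2 of ln X on t; flat data count as a perfect fit."""
    res = stats.linregress(t, ln_x)
    sst = float(np.sum((ln_x - ln_x.mean()) ** 2))
    if sst == 0.0:
        return 0.0, 1.0  # exactly flat: slope 0, residuals 0
    return float(res.slope), float(res.rvalue**2)


def estimate_mu(
    series: TimeSeries,
    min_window: int = 3,
    detection_floor: float = 0.01,
) -> GrowthRateEstimate:
    """Estimate mu (1/h) as the best log-linear window slope.

    Scans all contiguous windows of >= ``min_window`` points above
    ``detection_floor`` and returns the slope of the max-R^2 window
    (ties: longer window, then earlier start).  mu can be negative when
    the best window sits in the decline phase; callers filter if needed.
    """
    if series.quantity != "biomass":
        raise DomainError("growth-rate estimation requires a biomass series")
    if min_window < 3:
        raise DomainError("min_window must be >= 3")

    t_all = series.t_array()
    v_all = series.v_array()
    keep = v_all > detection_floor
    t = t_all[keep]
    v = v_all[keep]
    if t.size < min_window:
        raise InsufficientDataError(
            f"only {t.size} points above the detection floor "
            f"({detection_floor}); need >= {min_window}"
        )
    ln_x = np.log(v)

    best = None  # (r2_rounded, n_points, -start_index, slope, i, j, r2)
    n = t.size
    for i in range(n - min_window + 1):
        for j in range(i + min_window, n + 1):
            slope, r2 = _log_linear_fit(t[i:j], ln_x[i:j])
            key = (round(r2, _R2_TIE_DECIMALS), j - i, -i)
            if best is None or key > best[0]:
                best = (key, slope, i, j, r2)

    _, slope, i, j, r2 = best
    return GrowthRateEstimate(
        mu=slope,
        window_start=float(t[i]),
        window_end=float(t[j - 1]),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        n_points=j - i,
    )


def estimate_mu_replicates(
    replicates: Sequence[TimeSeries],
    min_window: int = 3,
    detection_floor: float = 0.01,
) -> tuple[float, float, list[GrowthRateEstimate]]:
    """Per-replicate mu estimates combined as mean and SD.

    Mirrors a triplicate design: mu is estimated independently per
    replicate, then averaged.  Returns (mean, sd, per-replicate estimates);
    sd is NaN for a single replicate.
    """
    if not replicates:
        raise InsufficientDataError("no replicate series supplied")
    ests = [estimate_mu(s, min_window, detection_floor) for s in replicates]
    mus = np.array([e.mu for e in ests])
    sd = float(np.std(mus, ddof=1)) if len(mus) > 1 else math.nan
    return float(np.mean(mus)), sd, ests
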