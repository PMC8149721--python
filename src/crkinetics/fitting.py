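"""Nonlinear least-squares estimation of all kinetic parameters.

Three estimators:

* ``fit_rate_constant`` — pseudo-first/second-order decay constants by
  linearisation (ln C or 1/C against t), closed-form and therefore exactly
  checkable against two-point oracles;
* ``fit_haldane`` — the three Haldane-Andrews parameters by bounded,
  seeded multi-start trust-region least squares;
* ``fit_tertiary`` — the nine cross-inhibition constants of the
  three-substrate Monod law with the per-substrate base parameters held
  fixed (they come from the single/binary-substrate fits and are not free).

Multi-start protocol: the first start is a data-driven heuristic; the
remaining ``n_starts - 1`` are drawn log-uniformly over the bounds from a
generator seeded by the caller, one draw per start, so start sets nest as
``n_starts`` grows and the best-of-starts objective is monotone in it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence, Union

import numpy as np
from scipy import optimize, stats

from .errors import (
    ConvergenceError,
    DegenerateDataError,
    DomainError,
    InsufficientDataError,
)
from .growth import TimeSeries
from .models import (
    HaldaneParams,
    SubstrateState,
    TertiaryMonodParams,
    haldane_mu,
    tertiary_mu,
)

__all__ = [
    "RateFit",
    "FitResult",
    "fit_rate_constant",
    "fit_haldane",
    "fit_tertiary",
    "r_squared",
    "DETECTION_LIMIT",
    "DEFAULT_BOUNDS",
    "DEFAULT_N_STARTS",
]

logger = logging.getLogger(__name__)

#: concentrations at/below this (mg/L) are treated as non-detects
DETECTION_LIMIT = 0.05
#: default per-parameter search bounds for multi-start draws
DEFAULT_BOUNDS = (1e-6, 1e4)
DEFAULT_N_STARTS = 20


@dataclass(frozen=True)
class RateFit:
    """A fitted pseudo-order rate constant (one Table-1-style row)."""

    order: Literal["first", "second"]
    k: float
    r_squared: float
    C0_used: float
    n_points: int

    def __post_init__(self):
        if self.k < 0:
            raise DomainError("k must be >= 0")
        if not 0.0 <= self.r_squared <= 1.0:
            raise DomainError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multi-start nonlinear fit."""

    params: Union[HaldaneParams, TertiaryMonodParams]
    r_squared: float
    residual_norm: float
    converged: bool
    n_starts_used: int
    seed: int
    degenerate: bool = False
    warnings: tuple[str, ...] = field(default_factory=tuple)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot.

    SS_tot is about the observed mean.  Can be negative for fits worse
    than the mean; not clipped here (only RateFit reporting clips).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise DomainError("observed and predicted must share a length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateDataError("observed values are all identical")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


# --------------------------------------------------------------------------
# pseudo-order rate constants (linearised, closed form)
# --------------------------------------------------------------------------

def fit_rate_constant(
    series: TimeSeries,
    order: Literal["first", "second"],
    detection_limit: float = DETECTION_LIMIT,
) -> RateFit:
    """Fit a pseudo-order decay constant to a Cr(VI) time course.

    First order regresses ln C on t (k = -slope, C0 = exp(intercept));
    second order regresses 1/C on t (k = slope, C0 = 1/intercept).  R^2 is
    computed in the linearised space and clipped to [0, 1] for reporting;
    a regression pointing the wrong way (growth) is clipped to k = 0.
    Points at/below ``detection_limit`` are excluded — complete reduction
    produces zeros the transforms cannot accept.
    """
    if order not in ("first", "second"):
        raise DomainError(f"unknown order {order!r}")
    t_all = series.t_array()
    c_all = series.v_array()
    keep = c_all > detection_limit
    t, c = t_all[keep], c_all[keep]
    if t.size < 2:
        raise InsufficientDataError(
            f"only {t.size} points above the detection limit; need >= 2"
        )

    y = np.log(c) if order == "first" else 1.0 / c
    res = stats.linregress(t, y)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if sst == 0.0 else float(res.rvalue**2)

    if order == "first":
        k = -float(res.slope)
        c0 = float(np.exp(res.intercept))
    else:
        k = float(res.slope)
        c0 = float(1.0 / res.intercept) if res.intercept != 0 else float(c[0])
    if k < 0:
        k, r2 = 0.0, 0.0  # decay model cannot represent growth

    return RateFit(
        order=order,
        k=k,
        r_squared=float(min(max(r2, 0.0), 1.0)),
        C0_used=c0,
        n_points=int(t.size),
    )


# --------------------------------------------------------------------------
# multi-start machinery
# --------------------------------------------------------------------------

def _multistart_least_squares(
    residual_fn,
    heuristic_x0: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    n_starts: int,
    seed: int,
    x_scale="jac",
):
    """Best-of-starts bounded least squares with nested seeded start sets."""
    rng = np.random.default_rng(seed)
    dim = heuristic_x0.size
    # sampling window: positive even where the fit bound allows exactly 0
    lo_s = np.maximum(lower, DEFAULT_BOUNDS[0])
    hi_s = np.minimum(np.where(np.isfinite(upper), upper, DEFAULT_BOUNDS[1]),
                      DEFAULT_BOUNDS[1])
    starts = [np.clip(heuristic_x0, lo_s, hi_s)]
    for _ in range(max(n_starts - 1, 0)):
        u = rng.random(dim)
        starts.append(np.exp(np.log(lo_s) + u * (np.log(hi_s) - np.log(lo_s))))

    best, diagnostics = None, []
    for idx, x0 in enumerate(starts):
        try:
            sol = optimize.least_squares(
                residual_fn, x0, bounds=(lower, upper), method="trf",
                x_scale=x_scale, ftol=1e-14, xtol=1e-14, gtol=1e-14,
                max_nfev=2000,
            )
        except Exception as exc:  # noqa: BLE001 — collected as diagnostics
            diagnostics.append((idx, repr(exc)))
            continue
        if not np.all(np.isfinite(sol.x)) or not math.isfinite(sol.cost):
            diagnostics.append((idx, "non-finite solution"))
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise ConvergenceError(
            f"all {len(starts)} starts failed", diagnostics=diagnostics
        )
    return best, len(starts), diagnostics


# --------------------------------------------------------------------------
# Haldane-Andrews fit
# --------------------------------------------------------------------------

def fit_haldane(
    mu_obs: Sequence[tuple[float, float]],
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
) -> FitResult:
    """Estimate (mu_max, K_S, K_I) from (S, mu) observations.

    Bounded multi-start trust-region least squares on the Haldane-Andrews
    residuals; at least 4 distinct S values are required for the 3 free
    parameters.  An all-zero mu signal converges to the lower bound and is
    flagged ``degenerate``.
    """
    S = np.array([s for s, _ in mu_obs], dtype=float)
    mu = np.array([m for _, m in mu_obs], dtype=float)
    if np.unique(S).size < 4:
        raise InsufficientDataError("need >= 4 distinct substrate levels")
    if np.any(S < 0):
        raise DomainError("substrate concentrations must be >= 0")

    def residuals(x):
        mu_max, K_S, K_I = x
        return mu_max * S / (S + S**2 / K_I + K_S) - mu

    mu_pos = mu[mu > 0]
    heuristic = np.array([
        1.5 * mu_pos.max() if mu_pos.size else 1.0,
        max(np.median(S[S > 0]) / 2.0, bounds[0]) if np.any(S > 0) else 1.0,
        max(2.0 * np.median(S[S > 0]), bounds[0]) if np.any(S > 0) else 1.0,
    ])
    lower = np.full(3, bounds[0])
    upper = np.full(3, bounds[1])
    best, n_used, diag = _multistart_least_squares(
        residuals, heuristic, lower, upper, n_starts, seed
    )

    params = HaldaneParams(mu_max=float(best.x[0]), K_S=float(best.x[1]),
                           K_I=float(best.x[2]))
    degenerate = bool(np.all(mu == mu[0]))
    try:
        r2 = r_squared(mu, haldane_mu(params, S))
    except DegenerateDataError:
        r2, degenerate = 0.0, True
    result = FitResult(
        params=params,
        r_squared=float(r2),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=True,
        n_starts_used=n_used,
        seed=seed,
        degenerate=degenerate,
    )
    logger.info(
        "fit_haldane: mu_max=%.6g K_S=%.6g K_I=%.6g R2=%.5f (%d starts, %d failed)",
        params.mu_max, params.K_S, params.K_I, result.r_squared, n_used, len(diag),
    )
    return result


# --------------------------------------------------------------------------
# tertiary Monod interaction-constant fit
# --------------------------------------------------------------------------

def fit_tertiary(
    mu_obs: Sequence[tuple[SubstrateState, float]],
    base_params: TertiaryMonodParams,
    form_variant: str | None = None,
    bounds: tuple[float, float] = (0.0, DEFAULT_BOUNDS[1]),
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
) -> FitResult:
    """Estimate the nine cross-inhibition constants, base parameters frozen.

    ``base_params`` supplies mu_max/K_S per substrate (its own interaction
    values are ignored as start values are searched over ``bounds``).
    Requires >= 10 observations; a design with no variation in some
    substrate yields an identifiability warning on the result.
    """
    if len(mu_obs) < 10:
        raise InsufficientDataError("need >= 10 observations for 9 free constants")
    states = [s for s, _ in mu_obs]
    mu = np.array([m for _, m in mu_obs], dtype=float)
    variant = form_variant or base_params.form_variant
    template = TertiaryMonodParams(
        base_C=base_params.base_C, base_P=base_params.base_P,
        base_h=base_params.base_h, form_variant=variant,
    )

    warnings = []
    for name, vals in zip(
        ("glucose S_C", "Cr(VI) S_P", "HCIF S_h"),
        zip(*(s.as_tuple() for s in states)),
    ):
        if np.unique(vals).size < 2:
            warnings.append(f"no variation in {name}: interaction constants "
                            "involving it are not identifiable")

    def residuals(x):
        p = template.with_interactions(x)
        return np.array([tertiary_mu(p, s) for s in states]) - mu

    heuristic = np.full(9, 1e-3)
    lower = np.full(9, bounds[0])
    upper = np.full(9, bounds[1])
    best, n_used, diag = _multistart_least_squares(
        residuals, heuristic, lower, upper, n_starts, seed
    )

    params = template.with_interactions(best.x)
    try:
        pred = np.array([tertiary_mu(params, s) for s in states])
        r2 = r_squared(mu, pred)
        degenerate = False
    except DegenerateDataError:
        r2, degenerate = 0.0, True
    result = FitResult(
        params=params,
        r_squared=float(r2),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=True,
        n_starts_used=n_used,
        seed=seed,
        degenerate=degenerate,
        warnings=tuple(warnings),
    )
    logger.info(
        "fit_tertiary: R2=%.5f residual_norm=%.3g (%d starts, %d failed)%s",
        result.r_squared, result.residual_norm, n_used, len(diag),
        " [identifiability warnings]" if warnings else "",
    )
    return result
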