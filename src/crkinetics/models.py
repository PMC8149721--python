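"""Forward growth and decay laws for Cr(VI) cometabolism kinetics.

Pure, side-effect-free evaluation of:

* the Haldane-Andrews substrate-inhibition growth law
      mu(S) = mu_max * S / (S + S^2/K_I + K_S),
  unimodal in S with its interior maximum at S* = sqrt(K_S * K_I);
* a three-substrate Monod growth law for cometabolic growth on glucose (C),
  Cr(VI) (P) and high-carbon iron filings, HCIF (h), in which each
  substrate's Monod term is inhibited by the other two substrates singly
  (K2, K3) and jointly (K4) — nine cross-inhibition constants in total;
* pseudo-first-order and pseudo-second-order pollutant decay,
      C(t) = C0 * exp(-k t)   and   C(t) = C0 / (1 + k C0 t).

All rates are per hour; concentrations are mg/L. HCIF, a solid dose, is
represented throughout as a pseudo-concentration (g dosed per litre of
reactor liquid, expressed in mg/L; 1 g per 250 mL -> 4000 mg/L).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Union

import numpy as np

from .errors import DomainError

__all__ = [
    "HaldaneParams",
    "MonodBase",
    "SubstrateState",
    "TertiaryMonodParams",
    "RateLawParams",
    "haldane_mu",
    "haldane_peak",
    "tertiary_mu",
    "rate_law_predict",
    "HCIF_PSEUDO_CONC",
]

#: 1 g HCIF per 250 mL expressed as a pseudo-concentration in mg/L.
HCIF_PSEUDO_CONC = 4000.0

ArrayLike = Union[float, np.ndarray]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise DomainError(msg)


@dataclass(frozen=True)
class HaldaneParams:
    """Haldane-Andrews parameters for one substrate.

    mu_max : maximum specific growth rate, 1/h
    K_S    : half-saturation (affinity) constant, mg/L
    K_I    : substrate self-inhibition constant, mg/L
    """

    mu_max: float
    K_S: float
    K_I: float

    def __post_init__(self):
        _require(self.mu_max > 0, f"mu_max must be > 0, got {self.mu_max}")
        _require(self.K_S > 0, f"K_S must be > 0, got {self.K_S}")
        _require(self.K_I > 0, f"K_I must be > 0, got {self.K_I}")

    @property
    def S_star(self) -> float:
        """Substrate concentration at the growth-rate maximum, sqrt(K_S*K_I)."""
        return float(np.sqrt(self.K_S * self.K_I))


@dataclass(frozen=True)
class MonodBase:
    """Single-substrate Monod base parameters (mu_max in 1/h, K_S in mg/L)."""

    mu_max: float
    K_S: float

    def __post_init__(self):
        _require(self.mu_max > 0, f"mu_max must be > 0, got {self.mu_max}")
        _require(self.K_S > 0, f"K_S must be > 0, got {self.K_S}")


@dataclass(frozen=True)
class SubstrateState:
    """Concentrations of the three cometabolic substrates, mg/L.

    S_C : glucose (carbon source)
    S_P : Cr(VI) (pollutant)
    S_h : HCIF pseudo-concentration (dose per litre of reactor liquid)
    """

    S_C: float
    S_P: float
    S_h: float

    def __post_init__(self):
        for name in ("S_C", "S_P", "S_h"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.S_C, self.S_P, self.S_h)


FormVariant = Literal["as_printed", "symmetric"]

_INTERACTION_NAMES = (
    "K2_C", "K3_C", "K4_C",
    "K2_P", "K3_P", "K4_P",
    "K2_h", "K3_h", "K4_h",
)


@dataclass(frozen=True)
class TertiaryMonodParams:
    """Three-substrate Monod growth law with nine cross-inhibition constants.

    Each substrate i in {C: glucose, P: Cr(VI), h: HCIF} contributes a term

        mu_max_i * S_i / (K_S_i + S_i + K2_i*S_j + K3_i*S_k + K4_i*S_j*S_k)

    where K2_i and K3_i (dimensionless per mg/L of the inhibiting substrate)
    quantify inhibition of substrate-i consumption by each of the other two
    substrates singly and K4_i (per (mg/L)^2) their joint inhibition.

    ``form_variant`` selects the second (Cr) term's own-saturation argument:
    "symmetric" (default) uses S_P, consistent with the other two terms;
    "as_printed" uses S_C, reproducing the formula as typeset in the source
    model (a presumed typo, kept selectable for comparison).
    """

    base_C: MonodBase
    base_P: MonodBase
    base_h: MonodBase
    K2_C: float = 0.0
    K3_C: float = 0.0
    K4_C: float = 0.0
    K2_P: float = 0.0
    K3_P: float = 0.0
    K4_P: float = 0.0
    K2_h: float = 0.0
    K3_h: float = 0.0
    K4_h: float = 0.0
    form_variant: FormVariant = "symmetric"

    def __post_init__(self):
        for name in _INTERACTION_NAMES:
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(
            self.form_variant in ("as_printed", "symmetric"),
            f"unknown form_variant {self.form_variant!r}",
        )

    def interactions(self) -> dict[str, float]:
        """The nine cross-inhibition constants, in canonical order."""
        return {name: getattr(self, name) for name in _INTERACTION_NAMES}

    def with_interactions(self, values) -> "TertiaryMonodParams":
        """Copy with the nine interaction constants replaced (canonical order)."""
        vals = dict(zip(_INTERACTION_NAMES, np.asarray(values, dtype=float)))
        return TertiaryMonodParams(
            base_C=self.base_C, base_P=self.base_P, base_h=self.base_h,
            form_variant=self.form_variant, **vals,
        )


@dataclass(frozen=True)
class RateLawParams:
    """Pseudo-order decay-law parameters.

    order : "first" (k in 1/h) or "second" (k in L/(mg h))
    k     : rate constant, >= 0
    C0    : initial concentration, mg/L
    """

    order: Literal["first", "second"]
    k: float
    C0: float

    def __post_init__(self):
        _require(self.order in ("first", "second"), f"unknown order {self.order!r}")
        _require(self.k >= 0, f"k must be >= 0, got {self.k}")
        _require(self.C0 > 0, f"C0 must be > 0, got {self.C0}")


# --------------------------------------------------------------------------
# forward evaluation
# --------------------------------------------------------------------------

def haldane_mu(params: HaldaneParams, S: ArrayLike) -> ArrayLike:
    """Specific growth rate mu(S) under Haldane-Andrews substrate inhibition.

    mu(S) = mu_max * S / (S + S^2/K_I + K_S); zero at S=0, unimodal with
    maximum mu_max / (1 + 2 sqrt(K_S/K_I)) at S = sqrt(K_S*K_I).
    """
    S_arr = np.asarray(S, dtype=float)
    if np.any(S_arr < 0):
        raise DomainError("substrate concentration S must be >= 0")
    mu = params.mu_max * S_arr / (S_arr + S_arr**2 / params.K_I + params.K_S)
    return float(mu) if np.isscalar(S) or S_arr.ndim == 0 else mu


def haldane_peak(params: HaldaneParams) -> tuple[float, float]:
    """(S*, mu(S*)) of the Haldane-Andrews law in closed form."""
    s_star = params.S_star
    mu_star = params.mu_max / (1.0 + 2.0 * np.sqrt(params.K_S / params.K_I))
    return s_star, float(mu_star)


def tertiary_mu(params: TertiaryMonodParams, state: SubstrateState) -> float:
    """Total specific growth rate on the glucose / Cr(VI) / HCIF mixture."""
    return float(sum(tertiary_mu_terms(params, state)))


def tertiary_mu_terms(
    params: TertiaryMonodParams, state: SubstrateState
) -> tuple[float, float, float]:
    """The three per-substrate growth-rate terms (glucose, Cr(VI), HCIF).

    Exposed separately so the batch simulator can apportion substrate
    consumption to the substrate that drives each term.
    """
    S_C, S_P, S_h = state.as_tuple()
    p = params

    den_C = p.base_C.K_S + S_C + p.K2_C * S_P + p.K3_C * S_h + p.K4_C * S_P * S_h
    term_C = p.base_C.mu_max * S_C / den_C

    own_P = S_C if p.form_variant == "as_printed" else S_P
    den_P = p.base_P.K_S + own_P + p.K2_P * S_C + p.K3_P * S_h + p.K4_P * S_C * S_h
    term_P = p.base_P.mu_max * S_P / den_P

    den_h = p.base_h.K_S + S_h + p.K2_h * S_C + p.K3_h * S_P + p.K4_h * S_C * S_P
    term_h = p.base_h.mu_max * S_h / den_h

    return float(term_C), float(term_P), float(term_h)


def rate_law_predict(params: RateLawParams, t: ArrayLike) -> ArrayLike:
    """Concentration C(t) under the pseudo-order decay law.

    First order: C0 * exp(-k t).  Second order: C0 / (1 + k C0 t), the
    integrated form of dC/dt = -k C^2.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("time t must be >= 0")
    if params.order == "first":
        c = params.C0 * np.exp(-params.k * t_arr)
    else:
        c = params.C0 / (1.0 + params.k * params.C0 * t_arr)
    return float(c) if np.isscalar(t) or t_arr.ndim == 0 else c
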