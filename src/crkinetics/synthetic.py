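"""Synthetic batch-reactor time courses and mu-vs-substrate datasets.

The study's raw curves exist only as figures, so every fitting stage in
this package is exercised against data from this generator instead.  A
batch reactor is modelled with four states — biomass X (OD600), glucose
S_C, Cr(VI) S_P and the HCIF pseudo-concentration S_h (all mg/L):

    dX/dt   = (mu(S) - k_d * phi(S_growth)) * X
    dS_C/dt = -mu_C(S) * X / Y_C
    dS_h/dt = -mu_h(S) * X / Y_h
    dS_P/dt = -q_P * X * S_P / (S_P + K_red)

mu(S) is the three-substrate Monod law (its glucose/HCIF terms mu_C, mu_h
apportion consumption), Y_* are biomass yields (OD per mg/L), q_P a
specific Cr(VI) reduction rate (mg/L per OD per h) and k_d a first-order
biomass decay that switches on as the growth substrates run out; the
exhaustion indicator is smoothed as phi = eps/(S_C + S_h + eps) to keep
the right-hand side Lipschitz.  These mass balances are the minimal
standard yield/Monod constructions — deliberately simple so that every
fitter has a known ground truth, not a mechanistic claim about Fe/Cr
chemistry.

Measurement noise is multiplicative Gaussian per replicate (triplicates
by default), drawn from a generator seeded in the config, and the
noise-free trajectory is always returned alongside.

Two calibration presets reproduce the qualitative milestones of the batch
experiments: ``set1_binary`` (glucose + bacteria; glucose spent by about
60 h, biomass declines after its peak, 100 mg/L Cr(VI) is only partially
reduced by 90 h) and ``set2_tertiary`` (glucose + HCIF + bacteria; growth
takes off near 50 h, glucose lasts to about 120 h, and even 100 mg/L
Cr(VI) is fully reduced by 120 h).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError, SimulationError
from .growth import TimeSeries
from .models import (
    HCIF_PSEUDO_CONC,
    HaldaneParams,
    MonodBase,
    SubstrateState,
    TertiaryMonodParams,
    haldane_mu,
    tertiary_mu_terms,
)

__all__ = [
    "BatchCondition",
    "SimulationConfig",
    "BatchSimulation",
    "simulate_batch",
    "generate_mu_dataset",
    "first_order_scenario",
    "preset_config",
    "preset_conditions",
    "DEFAULT_CR0_LEVELS",
    "PRESET_NAMES",
]

DEFAULT_CR0_LEVELS = (10.0, 25.0, 40.0, 50.0, 100.0)
#: g of dose per 250 mL of reactor liquid -> mg/L pseudo-concentration
_DOSE_TO_MGL = HCIF_PSEUDO_CONC
PRESET_NAMES = ("set1_binary", "set2_tertiary")


@dataclass(frozen=True)
class BatchCondition:
    """Design metadata for one batch reactor."""

    cr0: float
    glucose_dose: float = 1.0  # g per 250 mL
    hcif_dose: float = 1.0  # g per 250 mL; 0 for the binary system
    system: str = "tertiary"
    temperature: float = 35.0  # metadata only
    rpm: float = 120.0  # metadata only

    def __post_init__(self):
        if self.cr0 <= 0:
            raise DomainError("cr0 must be > 0")
        if self.glucose_dose < 0 or self.hcif_dose < 0:
            raise DomainError("doses must be >= 0")
        if self.system not in ("binary", "tertiary"):
            raise DomainError(f"unknown system {self.system!r}")
        if self.system == "binary" and self.hcif_dose != 0:
            raise DomainError("binary system must have hcif_dose = 0")

    @property
    def glucose0(self) -> float:
        """Initial glucose, mg/L."""
        return self.glucose_dose * _DOSE_TO_MGL

    @property
    def hcif0(self) -> float:
        """Initial HCIF pseudo-concentration, mg/L."""
        return self.hcif_dose * _DOSE_TO_MGL

    def condition_id(self) -> str:
        return f"{self.system}_cr{self.cr0:g}"


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the simulator needs besides the condition design."""

    growth_params: Union[TertiaryMonodParams, HaldaneParams]
    yield_C: float = 5.5e-4  # OD per mg/L glucose
    yield_h: float = 2.5e-4  # OD per mg/L HCIF pseudo-concentration
    q_P: float = 0.8  # mg/L Cr(VI) per OD per h
    K_red: float = 3.0  # mg/L, reduction saturation constant
    decay_rate: float = 0.02  # 1/h, post-exhaustion biomass decay
    exhaustion_eps: float = 20.0  # mg/L, smoothing scale of the decay switch
    x0: float = 0.02  # initial biomass, OD600
    noise_cv: float = 0.05  # relative SD of measurement noise
    n_replicates: int = 3
    seed: int = 0
    t_grid: tuple[float, ...] = tuple(float(t) for t in range(0, 121, 12))

    def __post_init__(self):
        if self.yield_C <= 0 or self.yield_h <= 0:
            raise DomainError("yields must be > 0")
        if min(self.q_P, self.K_red, self.decay_rate, self.noise_cv) < 0:
            raise DomainError("q_P, K_red, decay_rate, noise_cv must be >= 0")
        if self.x0 <= 0:
            raise DomainError("x0 must be > 0")
        if self.n_replicates < 1:
            raise DomainError("n_replicates must be >= 1")
        t = np.asarray(self.t_grid, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0) or t[0] < 0:
            raise DomainError("t_grid must be >= 0 and strictly increasing")
        object.__setattr__(self, "t_grid", tuple(float(x) for x in t))


@dataclass(frozen=True)
class BatchSimulation:
    """Noise-free trajectory plus noisy replicates for one condition."""

    condition: BatchCondition
    config: SimulationConfig
    noise_free: dict[str, TimeSeries]  # quantity -> series
    replicates: tuple[dict[str, TimeSeries], ...]

    def all_series(self) -> list[TimeSeries]:
        out = []
        for rep in self.replicates:
            out.extend(rep.values())
        return out


def _growth_terms(config: SimulationConfig, s_c: float, s_p: float, s_h: float):
    """(mu_C, mu_P, mu_h) shares of the specific growth rate."""
    gp = config.growth_params
    if isinstance(gp, HaldaneParams):
        # single-substrate scenario: growth on glucose only, self-inhibited
        return float(haldane_mu(gp, s_c)), 0.0, 0.0
    return tertiary_mu_terms(gp, SubstrateState(S_C=s_c, S_P=s_p, S_h=s_h))


def simulate_batch(
    condition: BatchCondition, config: SimulationConfig
) -> BatchSimulation:
    """Integrate the batch mass balances and sample noisy replicates.

    Returns the noise-free trajectory and ``n_replicates`` noisy copies,
    each value perturbed as v * (1 + noise_cv * z) with z ~ N(0, 1) and
    clipped at zero.  Bit-identical for identical condition + config.
    """
    t_grid = np.asarray(config.t_grid)
    y0 = [config.x0, condition.glucose0, condition.cr0, condition.hcif0]

    def rhs(_t, y):
        x, s_c, s_p, s_h = (max(v, 0.0) for v in y)
        mu_c, mu_p, mu_h = _growth_terms(config, s_c, s_p, s_h)
        mu_tot = mu_c + mu_p + mu_h
        phi = config.exhaustion_eps / (s_c + s_h + config.exhaustion_eps)
        dx = (mu_tot - config.decay_rate * phi) * x
        ds_c = -mu_c * x / config.yield_C
        ds_h = -mu_h * x / config.yield_h
        ds_p = -config.q_P * x * s_p / (s_p + config.K_red) if s_p > 0 else 0.0
        return [dx, ds_c, ds_p, ds_h]

    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
        method="LSODA", rtol=1e-8, atol=1e-10, max_step=6.0,
    )
    if not sol.success:
        raise SimulationError(
            f"ODE integration failed: {sol.message}",
            state={"t": sol.t.tolist(), "y": sol.y.tolist(), "y0": y0},
        )
    clean = np.clip(sol.y, 0.0, None)
    quantities = {"biomass": clean[0], "glucose": clean[1], "crvi": clean[2]}

    def mk(values, quantity, rep_id):
        return TimeSeries(times=tuple(t_grid), values=tuple(values),
                          quantity=quantity, replicate_id=rep_id)

    noise_free = {q: mk(v, q, "noise_free") for q, v in quantities.items()}
    rng = np.random.default_rng(config.seed)
    reps = []
    for r in range(config.n_replicates):
        rep = {}
        for q, v in quantities.items():
            z = rng.standard_normal(v.size)
            noisy = np.clip(v * (1.0 + config.noise_cv * z), 0.0, None)
            rep[q] = mk(noisy, q, f"rep{r + 1}")
        reps.append(rep)
    return BatchSimulation(condition=condition, config=config,
                           noise_free=noise_free, replicates=tuple(reps))


def generate_mu_dataset(
    model: Union[HaldaneParams, TertiaryMonodParams],
    design: Sequence,  # substrate levels (floats) or SubstrateState values
    noise_cv: float = 0.0,
    seed: int = 0,
):
    """Evaluate a growth law over a design and add relative Gaussian noise.

    For a Haldane model the design is a sequence of substrate levels and
    the output pairs are (S, mu); for the tertiary model it is a sequence
    of SubstrateState and the output pairs are (state, mu).  Same seed,
    same dataset.
    """
    if len(design) == 0:
        raise DomainError("design must be non-empty")
    if noise_cv < 0:
        raise DomainError("noise_cv must be >= 0")
    if isinstance(model, HaldaneParams):
        mu = np.array([haldane_mu(model, float(s)) for s in design])
    else:
        mu = np.array([sum(tertiary_mu_terms(model, s)) for s in design])
    rng = np.random.default_rng(seed)
    noisy = mu * (1.0 + noise_cv * rng.standard_normal(mu.size))
    return list(zip(list(design), [float(m) for m in noisy]))


# --------------------------------------------------------------------------
# calibration presets
# --------------------------------------------------------------------------

def _binary_growth_params() -> TertiaryMonodParams:
    # glucose-driven growth, mildly inhibited by Cr(VI); HCIF terms inert
    return TertiaryMonodParams(
        base_C=MonodBase(mu_max=0.1129, K_S=50.0),
        base_P=MonodBase(mu_max=0.002346, K_S=5.0),
        base_h=MonodBase(mu_max=0.1923, K_S=2000.0),
        K2_C=4.0, K3_C=0.0, K4_C=0.0,
        K2_P=1.0, K3_P=0.0, K4_P=0.0,
        K2_h=0.0, K3_h=0.0, K4_h=0.0,
    )


def _tertiary_growth_params() -> TertiaryMonodParams:
    # strong Cr(VI) inhibition of both growth substrates -> long lag that
    # relaxes as Cr(VI) is reduced; HCIF spares glucose consumption
    return TertiaryMonodParams(
        base_C=MonodBase(mu_max=0.1129, K_S=50.0),
        base_P=MonodBase(mu_max=0.002346, K_S=5.0),
        base_h=MonodBase(mu_max=0.1923, K_S=2000.0),
        K2_C=60.0, K3_C=2.5, K4_C=0.0,
        K2_P=1.0, K3_P=1.0, K4_P=0.0,
        K2_h=6.0, K3_h=50.0, K4_h=0.0,
    )


def preset_config(name: str, seed: int = 0, noise_cv: float = 0.05) -> SimulationConfig:
    """A frozen calibration preset: 'set1_binary' or 'set2_tertiary'."""
    if name == "set1_binary":
        return SimulationConfig(
            growth_params=_binary_growth_params(),
            yield_C=7.0e-4, yield_h=2.5e-4,
            q_P=0.8, K_red=3.0, decay_rate=0.02,
            x0=0.02, noise_cv=noise_cv, seed=seed,
        )
    if name == "set2_tertiary":
        return SimulationConfig(
            growth_params=_tertiary_growth_params(),
            yield_C=3.0e-4, yield_h=3.0e-4,
            q_P=2.5, K_red=3.0, decay_rate=0.02,
            x0=0.02, noise_cv=noise_cv, seed=seed,
        )
    raise DomainError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def first_order_scenario(
    cr0: float = 10.0, k: float = 0.05, seed: int = 0
) -> tuple[BatchCondition, SimulationConfig, float]:
    """A scenario whose noise-free Cr(VI) decay is (near-)exponential.

    Biomass is held effectively constant (negligible growth, no decay)
    and the reduction term operates far below saturation
    (K_red >> cr0), so dS_P/dt ~ -(q_P x0 / K_red) S_P.  Returns the
    condition, the config, and the calibrated first-order constant
    k = q_P * x0 / K_red (1/h) that a rate fit should recover.
    """
    x0 = 0.5
    K_red = 100.0 * cr0
    q_P = k * K_red / x0
    inert = TertiaryMonodParams(
        base_C=MonodBase(mu_max=1e-9, K_S=1.0),
        base_P=MonodBase(mu_max=1e-9, K_S=1.0),
        base_h=MonodBase(mu_max=1e-9, K_S=1.0),
    )
    cond = BatchCondition(cr0=cr0, system="binary", hcif_dose=0.0)
    cfg = SimulationConfig(
        growth_params=inert, q_P=q_P, K_red=K_red, decay_rate=0.0,
        x0=x0, noise_cv=0.0, seed=seed,
    )
    return cond, cfg, k


def preset_conditions(name: str) -> list[BatchCondition]:
    """The five-Cr(VI)-level condition set of a preset."""
    if name == "set1_binary":
        return [BatchCondition(cr0=c, hcif_dose=0.0, system="binary")
                for c in DEFAULT_CR0_LEVELS]
    if name == "set2_tertiary":
        return [BatchCondition(cr0=c, system="tertiary")
                for c in DEFAULT_CR0_LEVELS]
    raise DomainError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
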