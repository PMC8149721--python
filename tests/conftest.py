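import numpy as np
import pytest

from crkinetics.models import (
    HaldaneParams,
    MonodBase,
    SubstrateState,
    TertiaryMonodParams,
)

# Single-substrate Haldane parameter sets used as generating truth
# (mu_max, K_I reported by the study; K_S is a free choice of this package).
GLUCOSE_HALDANE = HaldaneParams(mu_max=0.1129, K_S=0.5, K_I=1.01)
CR_HALDANE = HaldaneParams(mu_max=0.002346, K_S=5.0, K_I=134.12)
HCIF_HALDANE = HaldaneParams(mu_max=0.1923, K_S=5.0, K_I=11.99)


@pytest.fixture
def tertiary_truth() -> TertiaryMonodParams:
    """A fully-interacting tertiary Monod truth for recovery tests."""
    return TertiaryMonodParams(
        base_C=MonodBase(mu_max=0.1129, K_S=50.0),
        base_P=MonodBase(mu_max=0.002346, K_S=5.0),
        base_h=MonodBase(mu_max=0.1923, K_S=2000.0),
        K2_C=60.0, K3_C=2.5, K4_C=0.01,
        K2_P=1.0, K3_P=1.0, K4_P=0.002,
        K2_h=6.0, K3_h=50.0, K4_h=0.005,
    )


@pytest.fixture
def factorial_design() -> list[SubstrateState]:
    """3x3x3 full factorial over realistic batch concentration ranges."""
    return [
        SubstrateState(c, p, h)
        for c in (1000.0, 2500.0, 4000.0)
        for p in (10.0, 50.0, 100.0)
        for h in (1000.0, 2500.0, 4000.0)
    ]


def haldane_design(params: HaldaneParams, n: int = 10) -> list[float]:
    """Log-spaced substrate grid spanning the Haldane peak."""
    s_star = params.S_star
    return list(np.geomspace(s_star / 30.0, s_star * 30.0, n))
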