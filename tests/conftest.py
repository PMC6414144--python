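"""Shared fixtures and the independent fixed-step integration oracle.

The oracle deliberately re-states the model equations on its own (rather
than importing the package's right-hand side) and integrates them with a
plain classical RK4 loop, so that agreement between the adaptive simulator
and the oracle checks both the equations and the integration."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from tricomp import GrowthParams, TransitionParams, TumorState  # noqa: E402

BREAST_GM = {"a": 0.56, "b": 0.0719}
LUNG_GM = {"a": 0.742, "b": 0.0792}
BREAST_3C = {"a": 0.653, "b": 0.0719}
LUNG_3C = {"a": 0.837, "b": 0.081}
TABLE_RATES = {"P12": 0.1, "P21": 0.1, "P13": 0.05, "P23": 0.05, "eta": 0.2}


@pytest.fixture
def breast_gm():
    return GrowthParams(**BREAST_GM)


@pytest.fixture
def breast_3c():
    return GrowthParams(**BREAST_3C), TransitionParams(**TABLE_RATES)


@pytest.fixture
def s0_fig3():
    return TumorState(t=0.0, T_A=500.0, T_Q=200.0, T_D=0.0)


def oracle_rhs(y, a, b, T_ref=1.0, P12=0.0, P21=0.0, P13=0.0, P23=0.0, eta=0.0):
    """Three-compartment growth rates, written directly from the equations."""
    TA, TQ, TD = y
    TA, TQ, TD = max(TA, 0.0), max(TQ, 0.0), max(TD, 0.0)
    growth = a * TA - b * TA * np.log(TA / T_ref) if TA > 1e-12 else 0.0
    return np.array(
        [
            growth - (P12 + P13) * TA + P21 * TQ,
            P12 * TA - (P21 + P23) * TQ,
            P13 * TA + P23 * TQ - eta * TD,
        ]
    )


def rk4_integrate(y0, t_total, h, rhs):
    """Classical fixed-step RK4 from 0 to ``t_total`` (``t_total/h`` integral)."""
    n = round(t_total / h)
    assert abs(n * h - t_total) < 1e-9 * max(1.0, t_total)
    y = np.asarray(y0, dtype=float)
    for _ in range(n):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * h * k1)
        k3 = rhs(y + 0.5 * h * k2)
        k4 = rhs(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


@pytest.fixture
def rk4():
    return rk4_integrate


@pytest.fixture
def oracle():
    return oracle_rhs
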