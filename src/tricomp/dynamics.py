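"""Untreated tumor growth: the Gompertz law and its three-compartment extension.

The Gompertz model describes a tumor whose specific growth rate decays with
the logarithm of its volume,

    dT/dt = a*T - b*T*ln(T / T_ref),

giving sigmoidal growth that saturates at the fixed point ``T_ref * exp(a/b)``.
The three-compartment (3-C) extension splits the tumor into dividing cells
``T_A`` (the only pool that proliferates, Gompertz-limited), quiescent cells
``T_Q`` (non-cycling but able to re-enter the cycle), and non-dividing cells
``T_D`` (doomed cells cleared passively at rate ``eta``), coupled by
first-order transition rates ``P12, P21, P13, P23``:

    dT_A/dt = a*T_A - b*T_A*ln(T_A/T_ref) - (P12 + P13)*T_A + P21*T_Q
    dT_Q/dt = P12*T_A - (P21 + P23)*T_Q
    dT_D/dt = P13*T_A + P23*T_Q - eta*T_D

Volumes are in cm^3, time in days, rates in 1/day throughout.  The model is
fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "T_FLOOR",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
    "GrowthParams",
    "TransitionParams",
    "TumorState",
    "Trajectory",
    "IntegrationError",
    "gompertz_rhs",
    "gompertz_closed_form",
    "carrying_capacity",
    "three_comp_rhs",
    "simulate_growth",
]

#: Volume (cm^3) below which a compartment is treated as eradicated: the
#: Gompertz term is defined as exactly 0 there, so ln(T) -> -inf can never
#: produce NaN/overflow during near-cure simulations.
T_FLOOR = 1e-12

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10

#: Sampled values more negative than this are an integrator failure rather
#: than round-off; smaller negative excursions are clamped to 0.
_NEG_CLAMP = 1e-7


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails or produces non-finite output."""


@dataclass(frozen=True)
class GrowthParams:
    """Gompertz growth constants.

    Parameters
    ----------
    a : float
        Growth coefficient (1/day).
    b : float
        Logarithmic damping coefficient (1/day).
    T_ref : float, default 1.0
        Reference volume (cm^3) inside the logarithm.  With ``T_ref = 1`` the
        carrying capacity is ``exp(a/b)``; setting ``T_ref`` to the initial
        volume ``T0`` instead yields the alternative capacity convention
        ``T0 * exp(a/b)``.  See :func:`carrying_capacity`.
    """

    a: float
    b: float
    T_ref: float = 1.0

    def __post_init__(self) -> None:
        if not (self.a >= 0 and math.isfinite(self.a)):
            raise ValueError(f"growth coefficient a must be >= 0, got {self.a}")
        if not (self.b >= 0 and math.isfinite(self.b)):
            raise ValueError(f"damping coefficient b must be >= 0, got {self.b}")
        if not (self.T_ref > 0 and math.isfinite(self.T_ref)):
            raise ValueError(f"reference volume T_ref must be > 0, got {self.T_ref}")


@dataclass(frozen=True)
class TransitionParams:
    """First-order transfer rates between the three cell compartments.

    ``P12``: dividing -> quiescent, ``P21``: quiescent -> dividing,
    ``P13``: dividing -> non-dividing, ``P23``: quiescent -> non-dividing,
    ``eta``: clearance of non-dividing cells.  All in 1/day.
    """

    P12: float = 0.0
    P21: float = 0.0
    P13: float = 0.0
    P23: float = 0.0
    eta: float = 0.0

    def __post_init__(self) -> None:
        for name in ("P12", "P21", "P13", "P23", "eta"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise ValueError(f"transition rate {name} must be >= 0, got {v}")

    @classmethod
    def zero(cls) -> "TransitionParams":
        """No inter-compartment exchange: the 3-C model degenerates to Gompertz."""
        return cls()


@dataclass(frozen=True)
class TumorState:
    """Compartment volumes (cm^3) at a time point ``t`` (days)."""

    t: float
    T_A: float
    T_Q: float = 0.0
    T_D: float = 0.0

    def __post_init__(self) -> None:
        for name in ("T_A", "T_Q", "T_D"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise ValueError(f"compartment volume {name} must be >= 0, got {v}")

    def total(self) -> float:
        """Total tumor volume ``T_A + T_Q + T_D``."""
        return self.T_A + self.T_Q + self.T_D

    def viable(self) -> float:
        """Viable (clonogenic) volume ``T_A + T_Q``; excludes doomed cells."""
        return self.T_A + self.T_Q

    def as_array(self) -> np.ndarray:
        return np.array([self.T_A, self.T_Q, self.T_D], dtype=float)

    @classmethod
    def from_array(cls, t: float, y: np.ndarray) -> "TumorState":
        return cls(t=float(t), T_A=float(y[0]), T_Q=float(y[1]), T_D=float(y[2]))


@dataclass
class Trajectory:
    """Time-ordered record of tumor states.

    ``times`` is non-decreasing; equal consecutive times occur only at
    radiation-fraction events, where the state immediately before and
    immediately after the fraction are both recorded.
    """

    times: np.ndarray
    states: np.ndarray  # shape (n, 3): columns T_A, T_Q, T_D
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2 or self.states.shape[1] != 3:
            raise ValueError("states must have shape (n, 3)")
        if len(self.times) != len(self.states):
            raise ValueError("times and states length mismatch")
        if len(self.times) == 0:
            raise ValueError("trajectory must contain at least one record")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("trajectory times must be non-decreasing")
        if np.any(self.states < 0):
            raise ValueError("trajectory states must be non-negative")

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self) -> Iterator[TumorState]:
        for t, y in zip(self.times, self.states):
            yield TumorState.from_array(t, y)

    @property
    def T_A(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def T_Q(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def T_D(self) -> np.ndarray:
        return self.states[:, 2]

    def total(self) -> np.ndarray:
        return self.states.sum(axis=1)

    def viable(self) -> np.ndarray:
        return self.states[:, :2].sum(axis=1)

    def initial(self) -> TumorState:
        return TumorState.from_array(self.times[0], self.states[0])

    def final(self) -> TumorState:
        return TumorState.from_array(self.times[-1], self.states[-1])

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with columns ``t, T_A, T_Q, T_D, total, viable``."""
        return pd.DataFrame(
            {
                "t": self.times,
                "T_A": self.T_A,
                "T_Q": self.T_Q,
                "T_D": self.T_D,
                "total": self.total(),
                "viable": self.viable(),
            }
        )

    def to_csv(self, path) -> None:
        """Write the trajectory as CSV at full float precision."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(
            times=df["t"].to_numpy(),
            states=df[["T_A", "T_Q", "T_D"]].to_numpy(),
        )


def _gompertz_term(T: float, p: GrowthParams) -> float:
    # Defined as exactly 0 at/below the eradication floor so that
    # -b*T*ln(T) -> 0 as T -> 0 without evaluating ln near zero.
    if T <= T_FLOOR:
        return 0.0
    return p.a * T - p.b * T * math.log(T / p.T_ref)


def gompertz_rhs(T: float, p: GrowthParams) -> float:
    """Gompertz growth rate ``a*T - b*T*ln(T/T_ref)`` in cm^3/day.

    Returns 0 for ``T`` at or below the eradication floor ``T_FLOOR``.
    """
    if T < 0:
        raise ValueError(f"tumor volume must be >= 0, got {T}")
    return _gompertz_term(T, p)


def gompertz_closed_form(T0: float, t, p: GrowthParams):
    """Exact solution of the Gompertz equation.

    ``T(t) = T_ref * exp(a/b + (ln(T0/T_ref) - a/b) * exp(-b*t))`` for
    ``b > 0``; pure exponential ``T0 * exp(a*t)`` when ``b == 0``.

    ``t`` may be a scalar or array of days; returns matching shape.
    """
    if not T0 > 0:
        raise ValueError(f"initial volume T0 must be > 0, got {T0}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    if p.b == 0:
        out = T0 * np.exp(p.a * t)
    else:
        ab = p.a / p.b
        out = p.T_ref * np.exp(ab + (math.log(T0 / p.T_ref) - ab) * np.exp(-p.b * t))
    return float(out) if out.ndim == 0 else out


def carrying_capacity(
    p: GrowthParams,
    T0: float | None = None,
    convention: str = "ode_fixed_point",
) -> float:
    """Asymptotic tumor volume of the Gompertz model.

    Two conventions are exposed and neither is asserted as canonical:

    ``"ode_fixed_point"``
        ``T_ref * exp(a/b)`` — the literal steady state of the ODE.
    ``"paper_formula"``
        ``T0 * exp(a/b)`` — a commonly quoted form in which the capacity
        scales with the initial volume ``T0``.  Equivalent to the fixed
        point of the ODE written with ``T_ref = T0``.
    """
    if p.b == 0:
        raise ValueError("carrying capacity undefined for b = 0 (unbounded growth)")
    ab = p.a / p.b
    if convention == "ode_fixed_point":
        return p.T_ref * math.exp(ab)
    if convention == "paper_formula":
        if T0 is None or not T0 > 0:
            raise ValueError("paper_formula convention requires T0 > 0")
        return T0 * math.exp(ab)
    raise ValueError(
        f"unknown convention {convention!r}; choose 'ode_fixed_point' or 'paper_formula'"
    )


def three_comp_rhs(
    s: TumorState, g: GrowthParams, tr: TransitionParams
) -> tuple[float, float, float]:
    """Right-hand side of the three-compartment growth ODE (cm^3/day).

    The Gompertz term acts on ``T_A`` only; the transition terms conserve
    volume among the compartments and ``eta`` drains ``T_D``.
    """
    dA = (
        _gompertz_term(s.T_A, g)
        - (tr.P12 + tr.P13) * s.T_A
        + tr.P21 * s.T_Q
    )
    dQ = tr.P12 * s.T_A - (tr.P21 + tr.P23) * s.T_Q
    dD = tr.P13 * s.T_A + tr.P23 * s.T_Q - tr.eta * s.T_D
    return (dA, dQ, dD)


def _rhs_array(y: np.ndarray, g: GrowthParams, tr: TransitionParams) -> np.ndarray:
    """Unvalidated vector RHS for the integrator; tolerates tiny negative
    excursions by evaluating terms on the non-negative part of the state."""
    T_A = y[0] if y[0] > 0 else 0.0
    T_Q = y[1] if y[1] > 0 else 0.0
    T_D = y[2] if y[2] > 0 else 0.0
    dA = _gompertz_term(T_A, g) - (tr.P12 + tr.P13) * T_A + tr.P21 * T_Q
    dQ = tr.P12 * T_A - (tr.P21 + tr.P23) * T_Q
    dD = tr.P13 * T_A + tr.P23 * T_Q - tr.eta * T_D
    return np.array([dA, dQ, dD])


def _sample_times(t_end: float, dt_out: float) -> np.ndarray:
    """Grid 0, dt_out, 2*dt_out, ..., always including t_end."""
    n = int(math.floor(t_end / dt_out + 1e-9))
    grid = np.arange(n + 1) * dt_out
    if grid[-1] < t_end - 1e-9 * max(1.0, t_end):
        grid = np.append(grid, t_end)
    else:
        grid[-1] = t_end
    return grid


def _integrate(
    y0: np.ndarray,
    t_span: tuple[float, float],
    t_eval: np.ndarray,
    g: GrowthParams,
    tr: TransitionParams,
    rtol: float,
    atol: float,
) -> np.ndarray:
    """solve_ivp wrapper returning states at ``t_eval``; raises on failure."""
    sol = solve_ivp(
        lambda t, y: _rhs_array(y, g, tr),
        t_span,
        y0,
        method="RK45",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    y = sol.y.T
    if not np.all(np.isfinite(y)):
        raise IntegrationError("ODE integration produced non-finite values")
    if np.any(y < -_NEG_CLAMP):
        raise IntegrationError(
            f"ODE integration produced negative volume {y.min():g} cm^3"
        )
    return np.clip(y, 0.0, None)


def simulate_growth(
    s0: TumorState,
    g: GrowthParams,
    tr: TransitionParams,
    t_end: float,
    dt_out: float = 0.1,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the untreated 3-C model from ``s0`` for ``t_end`` days.

    Uses an adaptive 8th-order Runge-Kutta method (DOP853) with relative
    tolerance ``rtol`` and absolute tolerance ``atol`` (cm^3); output is
    sampled every ``dt_out`` days.  Trajectory times are relative to ``s0.t``
    offset, i.e. absolute times ``s0.t, s0.t + dt_out, ...``.
    """
    if not t_end > 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    if not dt_out > 0:
        raise ValueError(f"dt_out must be > 0, got {dt_out}")
    rel = _sample_times(t_end, dt_out)
    y = _integrate(s0.as_array(), (0.0, t_end), rel, g, tr, rtol, atol)
    y[0] = s0.as_array()  # first record is the supplied initial state, exactly
    return Trajectory(
        times=s0.t + rel,
        states=y,
        metadata={"growth": g, "transitions": tr, "rtol": rtol, "atol": atol},
    )
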