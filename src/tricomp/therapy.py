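"""Radiation response: linear-quadratic cell kill and fractionated courses.

A delivered fraction of dose ``D`` (Gy) leaves a surviving fraction

    S(D) = exp(-(alpha*D + beta*D^2))

per compartment, with separate ``(alpha, beta)`` pairs for dividing and
quiescent cells; non-dividing cells are already doomed and receive no kill
term.  The rate form of the same law, ``dT/dt = -(alpha*D + 2*beta*D^2)*T``,
is the dose-derivative of the log-survival and is used when a fraction is
resolved as a finite beam-on window (:func:`finite_duration_fraction`).

A fractionated course alternates instantaneous kill events with untreated
3-C regrowth across the inter-fraction gaps — a piecewise integration in
which each fraction rescales ``T_A`` and ``T_Q`` and the growth ODE carries
the state to the next fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .dynamics import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    GrowthParams,
    IntegrationError,
    Trajectory,
    TransitionParams,
    TumorState,
    _gompertz_term,
    _integrate,
    _sample_times,
    three_comp_rhs,
)

__all__ = [
    "LQParams",
    "Schedule",
    "lq_survival",
    "treated_rhs",
    "apply_fraction",
    "run_course",
    "finite_duration_fraction",
]

_TIME_EPS = 1e-9


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic radiosensitivity of dividing and quiescent cells.

    ``alpha1, beta1`` (1/Gy, 1/Gy^2) apply to dividing cells, ``alpha2,
    beta2`` to quiescent cells.  The ratio ``alpha/beta`` (Gy) summarizes
    fractionation sensitivity: it is the dose at which linear and quadratic
    kill contribute equally.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float

    def __post_init__(self) -> None:
        for name in ("alpha1", "beta1", "alpha2", "beta2"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise ValueError(f"radiosensitivity {name} must be >= 0, got {v}")

    @property
    def alpha_beta_1(self) -> float | None:
        """alpha/beta ratio (Gy) of dividing cells, or None if beta1 == 0."""
        return self.alpha1 / self.beta1 if self.beta1 > 0 else None

    @property
    def alpha_beta_2(self) -> float | None:
        """alpha/beta ratio (Gy) of quiescent cells, or None if beta2 == 0."""
        return self.alpha2 / self.beta2 if self.beta2 > 0 else None

    @classmethod
    def from_ratios(
        cls,
        ratio1: float,
        ratio2: float,
        beta1: float = 0.035,
        beta2: float = 0.035,
    ) -> "LQParams":
        """Build absolute coefficients from alpha/beta ratios at fixed beta.

        Published settings for this model quote only the ratios; the default
        ``beta = 0.035 / Gy^2`` pins the absolute scale (so ratio 10 gives
        ``alpha = 0.35 / Gy``).
        """
        if not (beta1 > 0 and beta2 > 0):
            raise ValueError("finite alpha/beta ratio requires beta > 0")
        if not (ratio1 > 0 and ratio2 > 0):
            raise ValueError("alpha/beta ratios must be > 0")
        return cls(
            alpha1=ratio1 * beta1, beta1=beta1, alpha2=ratio2 * beta2, beta2=beta2
        )

    @classmethod
    def zero(cls) -> "LQParams":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class Schedule:
    """An ordered radiotherapy course: fraction delivery times and doses.

    ``times`` are days from course start (strictly increasing), ``doses``
    the corresponding fraction doses in Gy.
    """

    times: tuple[float, ...]
    doses: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))
        if len(self.times) != len(self.doses):
            raise ValueError("times and doses must have equal length")
        if any(d < 0 for d in self.doses):
            raise ValueError("fraction doses must be >= 0")
        if any(t < 0 for t in self.times):
            raise ValueError("fraction times must be >= 0")
        if any(b - a <= 0 for a, b in zip(self.times, self.times[1:])):
            raise ValueError("fraction times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(zip(self.times, self.doses))

    def cumulative_dose(self) -> float:
        """Total physical dose of the course (Gy)."""
        return float(sum(self.doses))

    @classmethod
    def uniform(
        cls, dose: float, n: int, gap: float = 1.0, start: float = 0.0
    ) -> "Schedule":
        """``n`` equal fractions of ``dose`` Gy every ``gap`` days from ``start``."""
        if n < 1:
            raise ValueError(f"number of fractions must be >= 1, got {n}")
        if dose < 0:
            raise ValueError(f"dose must be >= 0, got {dose}")
        if not gap > 0:
            raise ValueError(f"inter-fraction gap must be > 0, got {gap}")
        return cls(
            times=tuple(start + i * gap for i in range(n)), doses=(dose,) * n
        )

    @classmethod
    def empty(cls) -> "Schedule":
        return cls(times=(), doses=())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_days": self.times, "dose_gy": self.doses}).to_csv(
            path, index=False, float_format="%.17g"
        )

    @classmethod
    def from_csv(cls, path) -> "Schedule":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(
            times=tuple(df["time_days"].tolist()), doses=tuple(df["dose_gy"].tolist())
        )


def lq_survival(D: float, alpha: float, beta: float) -> float:
    """Surviving fraction ``exp(-(alpha*D + beta*D^2))`` after dose ``D`` Gy."""
    if D < 0:
        raise ValueError(f"dose must be >= 0, got {D}")
    return math.exp(-(alpha * D + beta * D * D))


def treated_rhs(
    s: TumorState,
    g: GrowthParams,
    tr: TransitionParams,
    lq: LQParams,
    D: float,
    kill_to_td: bool = False,
) -> tuple[float, float, float]:
    """3-C growth rates with radiation kill at dose context ``D``.

    The kill terms ``-(alpha*D + 2*beta*D^2)*T`` act on the dividing and
    quiescent pools only.  By default killed volume leaves the system
    outright; with ``kill_to_td=True`` it is routed into the non-dividing
    pool instead, so shrinkage becomes limited by the clearance rate.
    """
    dA, dQ, dD = three_comp_rhs(s, g, tr)
    kA = (lq.alpha1 * D + 2 * lq.beta1 * D * D) * s.T_A
    kQ = (lq.alpha2 * D + 2 * lq.beta2 * D * D) * s.T_Q
    dA -= kA
    dQ -= kQ
    if kill_to_td:
        dD += kA + kQ
    return (dA, dQ, dD)


def apply_fraction(
    s: TumorState, D: float, lq: LQParams, kill_to_td: bool = False
) -> TumorState:
    """Instantaneous delivery of one fraction of dose ``D`` Gy.

    ``T_A`` and ``T_Q`` are rescaled by their linear-quadratic surviving
    fractions; time is unchanged.  With ``kill_to_td=True`` the killed volume
    is moved into ``T_D`` rather than removed.
    """
    sA = lq_survival(D, lq.alpha1, lq.beta1)
    sQ = lq_survival(D, lq.alpha2, lq.beta2)
    killed = s.T_A * (1 - sA) + s.T_Q * (1 - sQ)
    return TumorState(
        t=s.t,
        T_A=s.T_A * sA,
        T_Q=s.T_Q * sQ,
        T_D=s.T_D + killed if kill_to_td else s.T_D,
    )


def run_course(
    s0: TumorState,
    g: GrowthParams,
    tr: TransitionParams,
    lq: LQParams,
    sched: Schedule,
    t_end: float,
    dt_out: float = 0.1,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    kill_to_td: bool = False,
) -> Trajectory:
    """Simulate a fractionated radiotherapy course.

    Alternates (i) instantaneous fraction application at each scheduled time
    and (ii) untreated 3-C regrowth across each inter-fraction gap and the
    post-course tail.  The trajectory records the state immediately before
    and immediately after every fraction (two rows at the same time), plus
    regular samples every ``dt_out`` days on a grid anchored at course start.

    ``t_end`` is measured in days from ``s0.t`` and must reach the last
    fraction; ``t_end`` equal to the last fraction time ends the course at
    the post-fraction state with no regrowth tail.
    """
    if not dt_out > 0:
        raise ValueError(f"dt_out must be > 0, got {dt_out}")
    if len(sched) and sched.times[-1] > t_end + _TIME_EPS:
        raise ValueError(
            f"last fraction at t={sched.times[-1]} lies beyond t_end={t_end}"
        )
    if not t_end >= 0:
        raise ValueError(f"t_end must be >= 0, got {t_end}")
    if t_end == 0 and len(sched) == 0:
        raise ValueError("t_end must be > 0 for an untreated run")

    grid = _sample_times(t_end, dt_out) if t_end > 0 else np.array([0.0])
    rec_t: list[float] = [0.0]
    rec_y: list[np.ndarray] = [s0.as_array()]
    t_cur = 0.0
    y_cur = s0.as_array()

    def advance(t_to: float) -> None:
        """Grow untreated from t_cur to t_to, recording grid samples and t_to."""
        nonlocal t_cur, y_cur
        if t_to <= t_cur + _TIME_EPS:
            return
        interior = grid[(grid > t_cur + _TIME_EPS) & (grid < t_to - _TIME_EPS)]
        t_eval = np.concatenate(([t_cur], interior, [t_to]))
        y = _integrate(y_cur, (t_cur, t_to), t_eval, g, tr, rtol, atol)
        for ti, yi in zip(t_eval[1:], y[1:]):
            rec_t.append(float(ti))
            rec_y.append(yi)
        t_cur = t_to
        y_cur = y[-1]

    for t_f, D in sched:
        advance(t_f)
        post = apply_fraction(
            TumorState.from_array(t_cur, y_cur), D, lq, kill_to_td=kill_to_td
        )
        y_cur = post.as_array()
        rec_t.append(t_cur)
        rec_y.append(y_cur)
    advance(t_end)

    return Trajectory(
        times=s0.t + np.array(rec_t),
        states=np.array(rec_y),
        metadata={
            "growth": g,
            "transitions": tr,
            "lq": lq,
            "schedule": sched,
            "rtol": rtol,
            "atol": atol,
            "kill_to_td": kill_to_td,
        },
    )


def finite_duration_fraction(
    s: TumorState,
    D: float,
    duration: float,
    g: GrowthParams,
    tr: TransitionParams,
    lq: LQParams,
    include_growth: bool = True,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> TumorState:
    """Deliver dose ``D`` over a finite beam-on window of ``duration`` days.

    The dose accumulates at constant rate ``D/duration``; the instantaneous
    log-kill rate is the dose-derivative ``(alpha + 2*beta*D_cum) * dD/dt``
    of the linear-quadratic survival, so with growth and transitions frozen
    the endpoint equals :func:`apply_fraction` exactly for any duration.
    With ``include_growth=True`` (default) growth and transitions act
    concurrently during the window.
    """
    if not duration > 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if D < 0:
        raise ValueError(f"dose must be >= 0, got {D}")
    rate = D / duration

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        T_A = y[0] if y[0] > 0 else 0.0
        T_Q = y[1] if y[1] > 0 else 0.0
        T_D = y[2] if y[2] > 0 else 0.0
        d_cum = rate * t
        kA = (lq.alpha1 + 2 * lq.beta1 * d_cum) * rate * T_A
        kQ = (lq.alpha2 + 2 * lq.beta2 * d_cum) * rate * T_Q
        if include_growth:
            dA = _gompertz_term(T_A, g) - (tr.P12 + tr.P13) * T_A + tr.P21 * T_Q
            dQ = tr.P12 * T_A - (tr.P21 + tr.P23) * T_Q
            dD = tr.P13 * T_A + tr.P23 * T_Q - tr.eta * T_D
        else:
            dA = dQ = dD = 0.0
        return np.array([dA - kA, dQ - kQ, dD])

    from scipy.integrate import solve_ivp

    sol = solve_ivp(
        rhs, (0.0, duration), s.as_array(), method="RK45", rtol=rtol, atol=atol
    )
    if not sol.success:
        raise IntegrationError(f"beam-on integration failed: {sol.message}")
    y_end = np.clip(sol.y[:, -1], 0.0, None)
    return TumorState.from_array(s.t + duration, y_end)
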