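"""Packaged simulation studies: growth comparison and treatment sweeps.

Each study is a parameterized, deterministic reproduction of one of the
model's headline experiments:

* :func:`compare_growth_models` — untreated growth, classical Gompertz vs
  the three-compartment model, for a matched parameter pair;
* :func:`dose_sweep` — effect of fraction size, at fixed fraction count or
  fixed total dose;
* :func:`quiescent_sweep` — effect of the initial quiescent volume;
* :func:`alpha_beta_sweep` — effect of radiosensitivity (alpha/beta swept
  at fixed beta, which is this package's documented convention).

Sweep outputs are long-format tables (one row per run) holding the control
metrics of each course: end-of-course and minimum viable volume relative to
the initial viable volume, and the earliest sampled time at which the
relative viable volume reached the control threshold (5% by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import (
    ConfigError,
    EXPERIMENT_PRESETS,
    RunConfig,
    experiment_preset_config,
    parameter_preset,
)
from .dynamics import Trajectory, TumorState, simulate_growth
from .therapy import LQParams, Schedule, run_course

__all__ = [
    "ControlMetrics",
    "SweepResult",
    "GrowthComparison",
    "control_metrics",
    "compare_growth_models",
    "dose_sweep",
    "quiescent_sweep",
    "alpha_beta_sweep",
    "run_experiment_preset",
]

NOT_REACHED = "not reached"

_SWEEP_COLUMNS = [
    "run_id",
    "param_name",
    "param_value",
    "end_rel_viable",
    "min_rel_viable",
    "time_to_control_days",
    "cumulative_dose_gy",
]


@dataclass(frozen=True)
class ControlMetrics:
    """Tumor-control summary of one trajectory, relative to a baseline volume."""

    end_rel_viable: float
    min_rel_viable: float
    #: Earliest sampled time (days) with relative viable volume at or below
    #: the threshold; ``None`` when control was never reached.
    time_to_control: float | None


def control_metrics(
    traj: Trajectory, threshold: float = 0.05, baseline: float | None = None
) -> ControlMetrics:
    """Compute control metrics of ``traj``.

    ``baseline`` defaults to the trajectory's initial viable volume.  The
    time to control is the first *sampled* state at or below
    ``threshold * baseline`` (inclusive comparison, no interpolation; with
    the default 0.1-day sampling the discretization error is negligible).
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if baseline is None:
        baseline = float(traj.viable()[0])
    if not baseline > 0:
        raise ValueError(f"baseline volume must be > 0, got {baseline}")
    rel = traj.viable() / baseline
    hits = np.nonzero(rel <= threshold)[0]
    return ControlMetrics(
        end_rel_viable=float(rel[-1]),
        min_rel_viable=float(rel.min()),
        time_to_control=float(traj.times[hits[0]]) if hits.size else None,
    )


@dataclass
class SweepResult:
    """Long-format sweep table plus the underlying trajectories by run id."""

    table: pd.DataFrame
    trajectories: dict[str, Trajectory] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        df = self.table.copy()
        df["time_to_control_days"] = df["time_to_control_days"].map(
            lambda v: NOT_REACHED if v is None or (isinstance(v, float) and math.isnan(v)) else v
        )
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "SweepResult":
        df = pd.read_csv(path, float_precision="round_trip")
        # in-memory tables use NaN for "control never reached"
        df["time_to_control_days"] = df["time_to_control_days"].map(
            lambda v: math.nan if v == NOT_REACHED else float(v)
        )
        return cls(table=df)


def _sweep_row(
    run_id: str,
    param_name: str,
    param_value: float,
    traj: Trajectory,
    sched: Schedule,
    threshold: float,
    baseline: float | None = None,
) -> dict:
    m = control_metrics(traj, threshold=threshold, baseline=baseline)
    return {
        "run_id": run_id,
        "param_name": param_name,
        "param_value": param_value,
        "end_rel_viable": m.end_rel_viable,
        "min_rel_viable": m.min_rel_viable,
        "time_to_control_days": m.time_to_control,
        "cumulative_dose_gy": sched.cumulative_dose(),
    }


def _require(cfg: RunConfig, *sections: str) -> None:
    for s in sections:
        if getattr(cfg, s) is None:
            raise ConfigError(f"experiment requires a {s!r} config section")


def _course(cfg: RunConfig, initial: TumorState, sched: Schedule) -> Trajectory:
    t_end = sched.times[-1] if len(sched) else 0.0
    return run_course(
        initial,
        cfg.growth,
        cfg.transitions,
        cfg.lq,
        sched,
        t_end=t_end,
        dt_out=cfg.dt_out,
        rtol=cfg.rtol,
        atol=cfg.atol,
    )


@dataclass
class GrowthComparison:
    """Matched untreated runs of the Gompertz and 3-C models."""

    gm: Trajectory
    three_c: Trajectory
    #: Pointwise ratio of 3-C total volume to Gompertz volume.
    ratio: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.gm.times,
                "gm_total": self.gm.total(),
                "three_c_total": self.three_c.total(),
                "ratio": self.ratio,
            }
        )


def compare_growth_models(
    preset: str,
    t_end: float,
    dt_out: float = 0.1,
    T0: float = 1.0,
) -> GrowthComparison:
    """Run the Gompertz and 3-C models side by side for a tumor-site pair.

    ``preset`` is ``"breast"`` or ``"lung"`` (the experiment preset names
    ``fig2_breast``/``fig2_lung`` are accepted as aliases).  Both models
    start from a pure dividing-cell seed of ``T0`` cm^3.  ``t_end = 0``
    returns the bare initial states.
    """
    pair = {"fig2_breast": "breast", "fig2_lung": "lung"}.get(preset, preset)
    if pair not in ("breast", "lung"):
        raise ConfigError(
            f"unknown growth-comparison preset {preset!r}; "
            "available: breast, lung, fig2_breast, fig2_lung"
        )
    g_gm, tr_gm = parameter_preset(f"{pair}_gm")
    g_3c, tr_3c = parameter_preset(f"{pair}_3c")
    s0 = TumorState(t=0.0, T_A=T0)
    if t_end == 0:
        single = Trajectory(times=[0.0], states=[s0.as_array()])
        return GrowthComparison(gm=single, three_c=single, ratio=np.array([1.0]))
    gm = simulate_growth(s0, g_gm, tr_gm, t_end=t_end, dt_out=dt_out)
    tc = simulate_growth(s0, g_3c, tr_3c, t_end=t_end, dt_out=dt_out)
    return GrowthComparison(gm=gm, three_c=tc, ratio=tc.total() / gm.total())


def dose_sweep(
    doses,
    config: RunConfig,
    policy: str = "fixed_count",
    n_fractions: int | None = None,
    total_dose: float | None = None,
    gap: float = 1.0,
) -> SweepResult:
    """One fractionated course per dose-per-fraction value.

    ``policy="fixed_count"`` delivers ``n_fractions`` fractions at every
    dose; ``policy="fixed_total"`` varies the count so every course delivers
    ``total_dose`` Gy (each dose must divide it evenly).
    """
    doses = list(doses)
    if not doses:
        raise ValueError("doses must be non-empty")
    _require(config, "growth", "transitions", "lq", "initial")
    rows, trajs = [], {}
    for dose in doses:
        if policy == "fixed_count":
            if n_fractions is None:
                raise ValueError("fixed_count policy requires n_fractions")
            n = n_fractions
        elif policy == "fixed_total":
            if total_dose is None:
                raise ValueError("fixed_total policy requires total_dose")
            if dose <= 0:
                raise ValueError("fixed_total policy requires positive doses")
            n_exact = total_dose / dose
            n = round(n_exact)
            if abs(n_exact - n) > 1e-9 or n < 1:
                raise ValueError(
                    f"dose {dose} Gy does not divide total {total_dose} Gy "
                    "into a whole number of fractions"
                )
        else:
            raise ValueError(
                f"unknown policy {policy!r}; choose 'fixed_count' or 'fixed_total'"
            )
        sched = Schedule.uniform(dose=dose, n=n, gap=gap)
        traj = _course(config, config.initial, sched)
        run_id = f"dose_{dose:g}"
        rows.append(
            _sweep_row(run_id, "dose_gy", dose, traj, sched, config.control_threshold)
        )
        trajs[run_id] = traj
    return SweepResult(table=pd.DataFrame(rows, columns=_SWEEP_COLUMNS), trajectories=trajs)


def quiescent_sweep(vq_values, config: RunConfig, dose: float | None = None,
                    n_fractions: int | None = None, gap: float = 1.0) -> SweepResult:
    """One course per initial quiescent volume, all else fixed.

    The schedule comes from ``dose``/``n_fractions`` if given, else from the
    config's schedule section.  All runs share one underlying tumor (the
    config's initial state) and differ only in the quiescent load added to
    it, so their metrics are normalized by a *common* baseline — the base
    initial viable volume — making the rows directly comparable in absolute
    terms, exactly as growth curves plotted on one axis are.
    """
    vq_values = list(vq_values)
    if any(v < 0 for v in vq_values):
        raise ValueError("quiescent volumes must be >= 0")
    _require(config, "growth", "transitions", "lq", "initial")
    if dose is not None and n_fractions is not None:
        sched = Schedule.uniform(dose=dose, n=n_fractions, gap=gap)
    elif config.schedule is not None:
        sched = config.schedule
    else:
        raise ConfigError("quiescent_sweep needs a schedule (dose/n_fractions)")
    common_baseline = config.initial.viable()
    if not common_baseline > 0:
        raise ConfigError("quiescent_sweep needs a positive base viable volume")
    rows, trajs = [], {}
    for vq in vq_values:
        s0 = replace(config.initial, T_Q=float(vq))
        traj = _course(config, s0, sched)
        run_id = f"vq_{vq:g}"
        rows.append(
            _sweep_row(run_id, "initial_quiescent_cm3", vq, traj, sched,
                       config.control_threshold, baseline=common_baseline)
        )
        trajs[run_id] = traj
    return SweepResult(table=pd.DataFrame(rows, columns=_SWEEP_COLUMNS), trajectories=trajs)


def alpha_beta_sweep(pairs, config: RunConfig, dose: float | None = None,
                     n_fractions: int | None = None, gap: float = 1.0,
                     mode: str = "ratio") -> SweepResult:
    """One course per radiosensitivity setting.

    ``mode="ratio"`` (default): each pair is ``(alpha1/beta1, alpha2/beta2)``
    realized at the betas of the config's ``lq`` section, which must be
    positive — the sweep's convention is that beta stays fixed while alpha
    carries the ratio.  ``mode="alpha"``: each pair is ``(alpha1, alpha2)``
    used directly with the config's betas (which may be zero).
    """
    pairs = [tuple(p) for p in pairs]
    _require(config, "growth", "transitions", "lq", "initial")
    if dose is not None and n_fractions is not None:
        sched = Schedule.uniform(dose=dose, n=n_fractions, gap=gap)
    elif config.schedule is not None:
        sched = config.schedule
    else:
        raise ConfigError("alpha_beta_sweep needs a schedule (dose/n_fractions)")
    base = config.lq
    rows, trajs = [], {}
    for r1, r2 in pairs:
        if mode == "ratio":
            if not (base.beta1 > 0 and base.beta2 > 0):
                raise ValueError(
                    "a finite alpha/beta ratio cannot be realized with beta = 0"
                )
            lq = LQParams.from_ratios(r1, r2, beta1=base.beta1, beta2=base.beta2)
            run_id = f"ab_{r1:g}_{r2:g}"
            param_value = r2
            param_name = "alpha_beta_quiescent"
        elif mode == "alpha":
            lq = LQParams(alpha1=r1, beta1=base.beta1, alpha2=r2, beta2=base.beta2)
            run_id = f"alpha_{r1:g}_{r2:g}"
            param_value = r2
            param_name = "alpha_quiescent_per_gy"
        else:
            raise ValueError(f"unknown mode {mode!r}; choose 'ratio' or 'alpha'")
        cfg = replace(config, lq=lq)
        traj = _course(cfg, config.initial, sched)
        rows.append(
            _sweep_row(run_id, param_name, param_value, traj, sched,
                       config.control_threshold)
        )
        trajs[run_id] = traj
    return SweepResult(table=pd.DataFrame(rows, columns=_SWEEP_COLUMNS), trajectories=trajs)


def run_experiment_preset(name: str):
    """Run a packaged experiment preset by name.

    Returns a :class:`GrowthComparison` for the growth-comparison presets
    and a :class:`SweepResult` for the treatment sweeps.
    """
    if name not in EXPERIMENT_PRESETS:
        raise ConfigError(
            f"unknown experiment preset {name!r}; available: "
            f"{', '.join(EXPERIMENT_PRESETS)}"
        )
    cfg = experiment_preset_config(name)
    exp = dict(cfg.experiment)
    kind = exp.pop("name")
    if kind == "compare_growth":
        return compare_growth_models(
            exp["pair"], t_end=exp["t_end"], dt_out=cfg.dt_out
        )
    if kind == "dose_sweep":
        return dose_sweep(
            exp["doses"], cfg, policy=exp.get("policy", "fixed_count"),
            n_fractions=exp.get("n_fractions"), total_dose=exp.get("total_dose"),
            gap=exp.get("gap", 1.0),
        )
    if kind == "quiescent_sweep":
        return quiescent_sweep(
            exp["vq_values"], cfg, dose=exp.get("dose"),
            n_fractions=exp.get("n_fractions"), gap=exp.get("gap", 1.0),
        )
    if kind == "alpha_beta_sweep":
        return alpha_beta_sweep(
            exp["ratio_pairs"], cfg, dose=exp.get("dose"),
            n_fractions=exp.get("n_fractions"), gap=exp.get("gap", 1.0),
        )
    raise ConfigError(f"preset {name}: unknown experiment kind {kind!r}")
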