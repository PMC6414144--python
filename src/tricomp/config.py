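"""Configuration loading, validation, and the packaged preset registry.

Run configurations are structured YAML (JSON, being a YAML subset, is
accepted too) with sections ``growth``, ``transitions``, ``lq``,
``initial``, ``schedule``, ``integrator``, ``control`` and ``experiment``.
Unknown keys are rejected by name so a typo never silently falls back to a
default.  Two kinds of presets ship with the package:

* parameter presets (``breast_gm``, ``lung_gm``, ``breast_3c``,
  ``lung_3c``) — flat growth/transition constants for the two tumor sites;
* experiment presets (``fig2_breast``, ``fig2_lung``, ``fig3_dose_sweep``,
  ``fig4_vq_sweep``, ``fig5_ab_sweep``) — complete run configurations for
  the packaged simulation studies, carrying every published setting plus
  the documented fill-ins (absolute beta, initial dividing volume).
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dynamics import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    GrowthParams,
    TransitionParams,
    TumorState,
)
from .therapy import LQParams, Schedule

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "save_config",
    "make_uniform_schedule",
    "parameter_preset",
    "experiment_preset_config",
    "PARAMETER_PRESETS",
    "EXPERIMENT_PRESETS",
]

log = logging.getLogger("tricomp")

PARAMETER_PRESETS = ("breast_gm", "lung_gm", "breast_3c", "lung_3c")
EXPERIMENT_PRESETS = (
    "fig2_breast",
    "fig2_lung",
    "fig3_dose_sweep",
    "fig4_vq_sweep",
    "fig5_ab_sweep",
)

_SECTION_KEYS = {
    "growth": {"a", "b", "T_ref"},
    "transitions": {"P12", "P21", "P13", "P23", "eta"},
    "lq": {"alpha1", "beta1", "alpha2", "beta2"},
    "initial": {"t", "T_A", "T_Q", "T_D"},
    "schedule": {"dose", "n_fractions", "gap", "fractions"},
    "integrator": {"rtol", "atol", "dt_out"},
    "control": {"threshold"},
    "experiment": {
        "name",
        "pair",
        "t_end",
        "doses",
        "policy",
        "n_fractions",
        "total_dose",
        "gap",
        "dose",
        "vq_values",
        "ratio_pairs",
    },
}


class ConfigError(ValueError):
    """Invalid, unparseable, or unknown-key configuration input."""


def _check_keys(section: str, data: dict, source: str) -> None:
    allowed = _SECTION_KEYS[section]
    for key in data:
        if key not in allowed:
            raise ConfigError(
                f"{source}: unknown key {key!r} in section {section!r} "
                f"(allowed: {', '.join(sorted(allowed))})"
            )


@dataclass(frozen=True)
class RunConfig:
    """A fully validated simulation run: parameters, schedule, settings.

    Sections a given run does not need (e.g. ``lq`` for untreated growth)
    may be ``None``; operations requiring them raise a clear error.
    """

    growth: GrowthParams | None = None
    transitions: TransitionParams | None = None
    lq: LQParams | None = None
    initial: TumorState | None = None
    schedule: Schedule | None = None
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    dt_out: float = 0.1
    control_threshold: float = 0.05
    experiment: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rtol > 0 or not self.atol > 0:
            raise ConfigError("integrator tolerances must be > 0")
        if not self.dt_out > 0:
            raise ConfigError("dt_out must be > 0")
        if not 0 < self.control_threshold <= 1:
            raise ConfigError("control threshold must be in (0, 1]")

    def to_dict(self) -> dict:
        """Plain-dict form that round-trips through :func:`save_config`."""
        out: dict = {}
        if self.growth is not None:
            out["growth"] = {
                "a": self.growth.a,
                "b": self.growth.b,
                "T_ref": self.growth.T_ref,
            }
        if self.transitions is not None:
            tr = self.transitions
            out["transitions"] = {
                "P12": tr.P12, "P21": tr.P21, "P13": tr.P13,
                "P23": tr.P23, "eta": tr.eta,
            }
        if self.lq is not None:
            out["lq"] = {
                "alpha1": self.lq.alpha1, "beta1": self.lq.beta1,
                "alpha2": self.lq.alpha2, "beta2": self.lq.beta2,
            }
        if self.initial is not None:
            out["initial"] = {
                "t": self.initial.t, "T_A": self.initial.T_A,
                "T_Q": self.initial.T_Q, "T_D": self.initial.T_D,
            }
        if self.schedule is not None:
            out["schedule"] = {
                "fractions": [
                    {"time": t, "dose": d} for t, d in self.schedule
                ]
            }
        out["integrator"] = {
            "rtol": self.rtol, "atol": self.atol, "dt_out": self.dt_out
        }
        out["control"] = {"threshold": self.control_threshold}
        if self.experiment:
            out["experiment"] = dict(self.experiment)
        return out


def _parse_schedule(data: dict, source: str) -> Schedule:
    _check_keys("schedule", data, source)
    if "fractions" in data:
        if {"dose", "n_fractions"} & data.keys():
            raise ConfigError(
                f"{source}: schedule gives both an explicit fraction list "
                "and uniform-schedule keys"
            )
        fr = data["fractions"]
        for item in fr:
            extra = set(item) - {"time", "dose"}
            if extra:
                raise ConfigError(
                    f"{source}: unknown key {extra.pop()!r} in schedule fraction"
                )
        return Schedule(
            times=tuple(f["time"] for f in fr),
            doses=tuple(f["dose"] for f in fr),
        )
    try:
        return Schedule.uniform(
            dose=data["dose"],
            n=data["n_fractions"],
            gap=data.get("gap", 1.0),
        )
    except KeyError as e:
        raise ConfigError(f"{source}: uniform schedule requires key {e.args[0]!r}")


def _config_from_dict(raw: dict, source: str) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError(f"{source}: top level must be a mapping of sections")
    unknown = set(raw) - set(_SECTION_KEYS)
    if unknown:
        raise ConfigError(
            f"{source}: unknown section {sorted(unknown)[0]!r} "
            f"(allowed: {', '.join(sorted(_SECTION_KEYS))})"
        )
    kwargs: dict = {}
    try:
        if "growth" in raw:
            _check_keys("growth", raw["growth"], source)
            kwargs["growth"] = GrowthParams(**raw["growth"])
        if "transitions" in raw:
            _check_keys("transitions", raw["transitions"], source)
            kwargs["transitions"] = TransitionParams(**raw["transitions"])
        if "lq" in raw:
            _check_keys("lq", raw["lq"], source)
            kwargs["lq"] = LQParams(**raw["lq"])
        if "initial" in raw:
            _check_keys("initial", raw["initial"], source)
            kwargs["initial"] = TumorState(t=raw["initial"].get("t", 0.0), **{
                k: v for k, v in raw["initial"].items() if k != "t"
            })
        if "schedule" in raw:
            kwargs["schedule"] = _parse_schedule(raw["schedule"], source)
        if "integrator" in raw:
            _check_keys("integrator", raw["integrator"], source)
            ig = raw["integrator"]
            kwargs["rtol"] = ig.get("rtol", DEFAULT_RTOL)
            kwargs["atol"] = ig.get("atol", DEFAULT_ATOL)
            kwargs["dt_out"] = ig.get("dt_out", 0.1)
        if "control" in raw:
            _check_keys("control", raw["control"], source)
            kwargs["control_threshold"] = raw["control"].get("threshold", 0.05)
        if "experiment" in raw:
            _check_keys("experiment", raw["experiment"], source)
            kwargs["experiment"] = dict(raw["experiment"])
    except ValueError as e:
        if isinstance(e, ConfigError):
            raise
        raise ConfigError(f"{source}: {e}") from e
    cfg = RunConfig(**kwargs)
    log.info("loaded config %s: %s", source, cfg.to_dict())
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration from ``path``."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"{path}: parse failure: {e}") from e
    return _config_from_dict(raw, str(path))


def save_config(cfg: RunConfig, path) -> None:
    """Write ``cfg`` as YAML; ``load_config`` of the result is identical."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def make_uniform_schedule(dose: float, n: int, gap: float = 1.0) -> Schedule:
    """``n`` fractions of ``dose`` Gy at times 0, gap, 2*gap, ... days."""
    return Schedule.uniform(dose=dose, n=n, gap=gap)


def _preset_text(name: str) -> str:
    res = importlib.resources.files("tricomp").joinpath(f"presets/{name}.yaml")
    if not res.is_file():
        raise ConfigError(
            f"unknown preset {name!r}; available: "
            f"{', '.join(PARAMETER_PRESETS + EXPERIMENT_PRESETS)}"
        )
    return res.read_text()


def parameter_preset(name: str) -> tuple[GrowthParams, TransitionParams]:
    """Load a packaged parameter preset by name.

    Returns the growth constants and transition rates; pure-Gompertz presets
    (``*_gm``) carry all-zero transition rates.
    """
    if name not in PARAMETER_PRESETS:
        raise ConfigError(
            f"unknown parameter preset {name!r}; available: "
            f"{', '.join(PARAMETER_PRESETS)}"
        )
    raw = yaml.safe_load(_preset_text(name))
    growth_keys = {"a", "b", "T_ref"}
    g = GrowthParams(**{k: v for k, v in raw.items() if k in growth_keys})
    tr_raw = {k: v for k, v in raw.items() if k not in growth_keys}
    unknown = set(tr_raw) - _SECTION_KEYS["transitions"]
    if unknown:
        raise ConfigError(f"preset {name}: unknown key {unknown.pop()!r}")
    return g, TransitionParams(**tr_raw)


def experiment_preset_config(name: str) -> RunConfig:
    """Load a packaged experiment preset as a validated :class:`RunConfig`."""
    if name not in EXPERIMENT_PRESETS:
        raise ConfigError(
            f"unknown experiment preset {name!r}; available: "
            f"{', '.join(EXPERIMENT_PRESETS)}"
        )
    return _config_from_dict(yaml.safe_load(_preset_text(name)), f"preset:{name}")
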