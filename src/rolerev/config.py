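"""Structured-text (YAML) run configuration.

A config file has up to four sections -- ``params``, ``initial``,
``solver``, ``experiment`` -- each a flat key-value mapping.  Missing keys
fall back to the package defaults (the reference parameter set); unknown
keys are rejected by name.  Configurations round-trip through
``save_config``/``load_config`` without loss.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import InitialCondition, ModelParameters

__all__ = ["RunConfig", "load_config", "save_config"]

_SOLVER_KEYS = {"h", "T_max", "blowup_threshold", "snapshot_times", "clamp"}
_EXPERIMENT_KEYS = {"n", "seed", "model", "variant", "batch_size"}


@dataclass
class RunConfig:
    """Everything a run needs: parameters, initial condition, solver and
    experiment settings."""

    params: ModelParameters = field(default_factory=ModelParameters)
    initial: InitialCondition | None = None  # None -> reference profile
    h: float = 0.005
    T_max: float = 500.0
    blowup_threshold: float = 1000.0
    snapshot_times: tuple[float, ...] = ()
    clamp: bool = False
    n: int = 100
    seed: int = 0
    model: str = "pde"

    def initial_condition(self) -> InitialCondition:
        return self.initial or InitialCondition.default(self.params)

    def to_dict(self) -> dict:
        d: dict = {"params": self.params.to_dict()}
        if self.initial is not None:
            ic = dataclasses.asdict(self.initial)
            if ic.get("table") is None:
                ic.pop("table", None)
            else:
                ic["table"] = [list(ic["table"][0]), list(ic["table"][1])]
            d["initial"] = ic
        d["solver"] = {
            "h": self.h,
            "T_max": self.T_max,
            "blowup_threshold": self.blowup_threshold,
            "snapshot_times": list(self.snapshot_times),
            "clamp": self.clamp,
        }
        d["experiment"] = {"n": self.n, "seed": self.seed, "model": self.model}
        return d


def _check_keys(section: dict, allowed: set[str], name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in [{name}]: {sorted(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; errors name the offending key."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    _check_keys(raw, {"params", "initial", "solver", "experiment"}, "root")

    params = ModelParameters.from_dict(raw.get("params", {}))

    initial = None
    if "initial" in raw:
        sec = dict(raw["initial"])
        _check_keys(sec, {"x0", "levels", "breaks", "convention", "table"}, "initial")
        for key in ("levels", "breaks"):
            if key in sec:
                sec[key] = tuple(sec[key])
        if sec.get("table") is not None:
            ages, values = sec["table"]
            sec["table"] = (tuple(ages), tuple(values))
        initial = InitialCondition(**sec)

    cfg = RunConfig(params=params, initial=initial)
    solver = raw.get("solver", {})
    _check_keys(solver, _SOLVER_KEYS, "solver")
    for key, val in solver.items():
        if key == "snapshot_times":
            val = tuple(float(v) for v in val)
        setattr(cfg, key, val)
    if cfg.h <= 0:
        raise ValueError(f"solver key 'h' must be positive, got {cfg.h}")

    exp = raw.get("experiment", {})
    _check_keys(exp, _EXPERIMENT_KEYS, "experiment")
    for key in ("n", "seed", "model"):
        if key in exp:
            setattr(cfg, key, exp[key])
    if "variant" in exp:
        cfg.params = cfg.params.replace(variant=exp["variant"])
    if cfg.model not in ("pde", "ode", "dde"):
        raise ValueError(f"experiment key 'model' must be pde/ode/dde, got {cfg.model}")
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
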