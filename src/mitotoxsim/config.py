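"""Configuration schema, serialization and time-series output.

Run configuration is a nested document (YAML or JSON) with sections
``core`` / ``pk`` / ``etc_inhibition`` / ``redox_cycling`` / ``iron`` /
``mtdna`` / ``pathways`` / ``calibration`` / ``solver``.  Every field is
schema-validated (units documented on the dataclasses they mirror) and
unknown keys are rejected.  An empty file yields the shipped calibrated
defaults.

Conventions used by all files this package writes: time in hours, drug
concentrations in uM, mtDNA content unitless in [0, 1], ROS species
normalized to the drug-free baseline (see docs/UNITS.md).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .core import BioenergeticCore, CoreParams, default_core_params
from .mtdna import MtDNAParams
from .pathways import (ETCInhibitionParams, IronModel, PKParams,
                       PathwaySwitches, RedoxCyclingParams)
from .simulate import DoxToxicityModel, SimulationResult

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config",
           "build_model", "write_timeseries", "write_summary", "config_hash"]

_CORE_DEFAULTS = dataclasses.asdict(default_core_params())


class ConfigError(ValueError):
    """Raised on schema violations; message lists every offending key."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


CoreSection = type("CoreSection", (_Section,), {
    "__annotations__": {k: float for k in _CORE_DEFAULTS},
    **_CORE_DEFAULTS,
})


class PKSection(_Section):
    t_half_abs_min: float = 5.0
    t_half_elim_h: float = 24.0
    peak_norm: bool = True


class ETCInhibitionSection(_Section):
    ic50_I: float = 784.4
    ic50_II: float = 941.3
    ic50_III: float = 470.6
    ic50_IV: float = 1019.7
    hill_I: float = 2.25
    hill_II: float = 2.25
    hill_III: float = 2.25
    hill_IV: float = 2.25

    @field_validator("ic50_I", "ic50_II", "ic50_III", "ic50_IV",
                     "hill_I", "hill_II", "hill_III", "hill_IV")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"etc_inhibition.{info.field_name} must be positive")
        return v


class RedoxCyclingSection(_Section):
    eta: float = 0.007276


class IronSection(_Section):
    fe0: float = 1.0
    k_fe: float = 0.01
    chelation_windows: tuple[tuple[float, float], ...] = ()
    clear_half_time_h: float = 336.0


class MtDNASection(_Section):
    alpha: float = 0.0045
    kappa: float = 0.05
    gamma: float = 0.00165
    m0: float = 0.75
    oh_ceiling: float = 1e3


class PathwaysSection(_Section):
    etc_inhibition: bool = True
    redox_cycling: bool = True
    direct_mtdna_damage: bool = True
    ros_mtdna_damage: bool = True


class CalibrationSection(_Section):
    noise_sd: float = 0.03
    n_sweep_samples: int = 500
    acceptance_band_se: float = 2.0


class SolverSection(_Section):
    mode: str = "hybrid"            # chronic integrator: hybrid | full
    deriv_tol: float = 1e-8         # steady-state derivative tolerance
    follow_up_weeks: float = 40.0   # default chronic horizon
    seed: int = 0

    @field_validator("mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("hybrid", "full"):
            raise ValueError("solver.mode must be 'hybrid' or 'full'")
        return v


class RunConfig(_Section):
    core: CoreSection = CoreSection()
    pk: PKSection = PKSection()
    etc_inhibition: ETCInhibitionSection = ETCInhibitionSection()
    redox_cycling: RedoxCyclingSection = RedoxCyclingSection()
    iron: IronSection = IronSection()
    mtdna: MtDNASection = MtDNASection()
    pathways: PathwaysSection = PathwaysSection()
    calibration: CalibrationSection = CalibrationSection()
    solver: SolverSection = SolverSection()


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"])
        lines.append(f"{loc}: {err['msg']}")
    return "invalid configuration:\n  " + "\n  ".join(lines)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    An empty file produces the all-defaults configuration; any schema
    violation raises :class:`ConfigError` naming every offending key.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix.lower() not in (".json",) \
        else json.loads(text or "{}")
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(data).__name__}")
    try:
        cfg = RunConfig(**data)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from None
    # cross-field checks done by the runtime dataclasses
    try:
        build_model(cfg)
    except ValueError as exc:
        raise ConfigError(f"invalid configuration: {exc}") from None
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = cfg.model_dump()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of a configuration (logged in run headers)."""
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def build_model(cfg: RunConfig) -> DoxToxicityModel:
    """Instantiate the toxicity model a configuration describes."""
    core = BioenergeticCore(CoreParams(**cfg.core.model_dump()))
    return DoxToxicityModel(
        core=core,
        pk=PKParams(**cfg.pk.model_dump()),
        etc=ETCInhibitionParams(**cfg.etc_inhibition.model_dump()),
        rc=RedoxCyclingParams(**cfg.redox_cycling.model_dump()),
        iron=IronModel(**cfg.iron.model_dump()),
        mtdna=MtDNAParams(**cfg.mtdna.model_dump()),
        switches=PathwaySwitches(**cfg.pathways.model_dump()),
    )


def write_timeseries(result: SimulationResult, path: str | Path) -> Path:
    """Write a simulation result as CSV.

    Header: ``time_h``, one column per raw state/flux, then the
    baseline-normalized copies prefixed ``norm_``; full precision,
    deterministic column order.
    """
    if result.time_h.size == 0:
        raise ValueError("cannot write an empty simulation result")
    path = Path(path)
    frame = result.to_frame()
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def read_timeseries(path: str | Path) -> pd.DataFrame:
    # round_trip parsing: written values are exact 17-digit representations
    return pd.read_csv(path, float_precision="round_trip")


def write_summary(summary: dict, path: str | Path) -> Path:
    """JSON run summary (outcome labels, thresholds, attribution...)."""
    path = Path(path)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(summary, indent=2, sort_keys=True,
                               default=default) + "\n")
    return path
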