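"""Run configuration: unit-aware parameter loading, defaults, and round-trip IO.

Every concentration in a config file must declare a unit (``nM``, ``µM``/``uM``,
``mM`` or ``M``); the loader normalises everything to the internal nM/hour
system.  Unknown keys are rejected so a run is fully reproducible from its
config file alone, and every field filled from the packaged defaults is
logged.
"""

from __future__ import annotations

import logging
import re
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .kinetics import RateConstants
from .simulate import SimulationSettings

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "parse_quantity",
    "default_rate_constants",
    "default_initial_concentrations",
    "packaged_parameters",
    "setup_logging",
]

logger = logging.getLogger("braferk")

_NM_PER = {"nM": 1.0, "uM": 1e3, "µM": 1e3, "mM": 1e6, "M": 1e9}
_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([a-zA-Zµ/()*0-9]+)\s*$")


def parse_quantity(value: Any, kind: str = "concentration") -> float:
    """Parse ``"3 nM"`` / ``{value: 3, unit: nM}`` into nM (or 1/h, 1/(nM*h)).

    A bare number is an error for concentrations — units must be explicit.
    """
    if isinstance(value, Mapping):
        if "value" not in value or "unit" not in value:
            raise ValueError(f"quantity mapping needs 'value' and 'unit': {value!r}")
        num, unit = float(value["value"]), str(value["unit"])
    elif isinstance(value, str):
        m = _QUANTITY_RE.match(value)
        if not m:
            raise ValueError(f"cannot parse quantity {value!r}")
        num, unit = float(m.group(1)), m.group(2)
    elif isinstance(value, (int, float)) and kind == "rate":
        return float(value)  # rates default to the internal 1/h system
    else:
        raise ValueError(f"{kind} {value!r} has no unit; units are required")
    if kind == "concentration":
        if unit not in _NM_PER:
            raise ValueError(f"unknown concentration unit {unit!r}")
        out = num * _NM_PER[unit]
    elif kind == "rate":
        if unit not in ("1/h", "1/(nM*h)", "per_h", "per_nM_per_h"):
            raise ValueError(f"unknown rate unit {unit!r}")
        out = num
    else:  # pragma: no cover
        raise ValueError(kind)
    if out < 0:
        raise ValueError(f"{kind} must be nonnegative, got {num} {unit}")
    return out


def packaged_parameters() -> dict:
    """The shipped parameter file (rate constants + initial concentrations),
    parsed but not normalised; provenance flags included."""
    text = (resources.files("braferk") / "data" / "parameters.yaml").read_text("utf-8")
    return yaml.safe_load(text)


def default_rate_constants() -> RateConstants:
    raw = packaged_parameters()["rate_constants"]
    return RateConstants.from_mapping(
        {name: parse_quantity(entry, kind="rate") for name, entry in raw.items()})


def default_initial_concentrations() -> dict[str, float]:
    """Baseline free-pool concentrations in nM (BRAF 3 nM, ATP 1 mM, ...)."""
    raw = packaged_parameters()["initial_concentrations"]
    return {name: parse_quantity(entry) for name, entry in raw.items()}


class _SettingsModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t_end_h: float = 24.0
    readout_times_h: tuple[float, ...] = (8.0, 16.0, 24.0)
    rtol: float = 1e-8
    atol_nM: float = 1e-12
    clamp_atp: bool = False
    pre_equilibrate: bool = False

    def to_settings(self) -> SimulationSettings:
        return SimulationSettings(t_end=self.t_end_h,
                                  readout_times=self.readout_times_h,
                                  rtol=self.rtol, atol=self.atol_nM,
                                  clamp_atp=self.clamp_atp,
                                  pre_equilibrate=self.pre_equilibrate)


class _DosesModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dbf_uM: float = Field(0.0, ge=0)
    tmt_uM: float = Field(0.0, ge=0)


class RunConfig(BaseModel):
    """A fully validated, unit-normalised run configuration.

    ``rate_constants`` are in 1/h and 1/(nM·h); ``initial_concentrations`` in
    nM.  Unknown keys anywhere in the file are rejected.
    """

    model_config = ConfigDict(extra="forbid")

    rate_constants: dict[str, float]
    initial_concentrations: dict[str, float]
    doses: _DosesModel = _DosesModel()
    settings: _SettingsModel = _SettingsModel()
    include_dbf: bool = True
    include_tmt: bool = True
    output_dir: str | None = None
    log_level: str = "WARNING"

    @field_validator("rate_constants", "initial_concentrations")
    @classmethod
    def _nonnegative(cls, v: dict[str, float]) -> dict[str, float]:
        bad = {k: x for k, x in v.items() if x < 0}
        if bad:
            raise ValueError(f"negative values: {bad}")
        return v

    def constants(self) -> RateConstants:
        return RateConstants.from_mapping(self.rate_constants)

    def simulation_settings(self) -> SimulationSettings:
        return self.settings.to_settings()

    def model(self):
        from .network import build_cascade_network
        from .simulate import CascadeModel

        net = build_cascade_network(self.include_dbf, self.include_tmt)
        return CascadeModel(network=net, constants=self.constants(),
                            initial=self.initial_concentrations,
                            settings=self.simulation_settings())


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run config, filling gaps from the packaged
    defaults (each defaulted field is logged at INFO)."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config root must be a mapping, got {type(data).__name__}")

    defaults = packaged_parameters()
    raw_rates = dict(defaults["rate_constants"])
    defaulted = set(raw_rates) - set(data.get("rate_constants", {}))
    raw_rates.update(data.get("rate_constants", {}))
    rates = {k: parse_quantity(v, kind="rate") for k, v in raw_rates.items()}

    raw_conc = dict(defaults["initial_concentrations"])
    defaulted |= set(raw_conc) - set(data.get("initial_concentrations", {}))
    raw_conc.update(data.get("initial_concentrations", {}))
    concs = {k: parse_quantity(v) for k, v in raw_conc.items()}

    for name in sorted(defaulted):
        logger.info("config: %s defaulted from packaged parameter file", name)
    if "doses" not in data:
        logger.info("config: doses defaulted to 0 (drug-free)")

    merged = {k: v for k, v in data.items()
              if k not in ("rate_constants", "initial_concentrations")}
    merged["rate_constants"] = rates
    merged["initial_concentrations"] = concs
    return RunConfig(**merged)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Serialise a normalised config; save → load → save is byte-stable."""
    payload = config.model_dump(mode="json")
    # concentrations must round-trip with explicit units
    payload["initial_concentrations"] = {
        k: f"{float(v)} nM" for k, v in payload["initial_concentrations"].items()}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True, default_flow_style=False)


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    """Route package logs to stderr (and optionally a file)."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    log = logging.getLogger("braferk")
    log.setLevel(level.upper())
    for h in handlers:
        h.setFormatter(fmt)
        log.addHandler(h)
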