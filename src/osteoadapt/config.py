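"""YAML run configuration: one file describes a reproducible simulation.

Sections mirror the library types (femur, density, implant, loads,
materials, remodelling, scenario, output); CLI flags override the scalar
fields seed / total_months / scenario_kind.  Unknown keys are rejected so
typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .anatomy import DensityFieldParams, FemurParams, ImplantParams
from .materials import BoneMaterialLaw, CallusMaterial, ImplantMaterial
from .remodelling import RemodellingParams, ScenarioConfig

__all__ = ["ConfigError", "LoadSettings", "OutputSettings", "RunConfig",
           "load_config", "dump_config", "default_config"]


class ConfigError(ValueError):
    """Configuration file missing, unreadable, or schema-invalid."""


@dataclass(frozen=True)
class LoadSettings:
    body_weight: float = 450.0  # N
    profile: str = "walking"
    hip_peak_multiple: float | None = None
    abductor_peak_multiple: float | None = None


@dataclass(frozen=True)
class OutputSettings:
    snapshot_months: tuple[int, ...] = (1, 12, 13, 36)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    femur: FemurParams = field(default_factory=FemurParams)
    density: DensityFieldParams = field(default_factory=DensityFieldParams)
    implant: ImplantParams = field(default_factory=ImplantParams)
    loads: LoadSettings = field(default_factory=LoadSettings)
    bone_material: BoneMaterialLaw = field(default_factory=BoneMaterialLaw)
    implant_material: ImplantMaterial = field(default_factory=ImplantMaterial)
    callus_material: CallusMaterial = field(default_factory=CallusMaterial)
    remodelling: RemodellingParams = field(default_factory=RemodellingParams)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    output: OutputSettings = field(default_factory=OutputSettings)

    def with_overrides(self, seed=None, months=None, scenario=None) -> "RunConfig":
        cfg = self
        if seed is not None:
            cfg = dataclasses.replace(
                cfg,
                seed=int(seed),
                femur=dataclasses.replace(cfg.femur, seed=int(seed)),
                density=dataclasses.replace(cfg.density, seed=int(seed)),
            )
        sc = cfg.scenario
        if months is not None or scenario is not None or seed is not None:
            sc = dataclasses.replace(
                sc,
                total_months=int(months) if months is not None else sc.total_months,
                scenario_kind=scenario if scenario is not None else sc.scenario_kind,
                seed=int(seed) if seed is not None else sc.seed,
            )
            cfg = dataclasses.replace(cfg, scenario=sc)
        return cfg


_SECTIONS = {
    "femur": FemurParams,
    "density": DensityFieldParams,
    "implant": ImplantParams,
    "loads": LoadSettings,
    "bone_material": BoneMaterialLaw,
    "implant_material": ImplantMaterial,
    "callus_material": CallusMaterial,
    "remodelling": RemodellingParams,
    "output": OutputSettings,
}


def _build(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in section {section!r}: {sorted(unknown)}")
    coerced = {
        k: (tuple(v) if isinstance(v, list) else v) for k, v in data.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {section!r}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse YAML in {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping: {path}")
    known = set(_SECTIONS) | {"seed", "scenario"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {"seed": int(raw.get("seed", 0))}
    for section, cls in _SECTIONS.items():
        if section in raw:
            if not isinstance(raw[section], dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            kwargs[section] = _build(cls, raw[section], section)
    if "scenario" in raw:
        data = dict(raw["scenario"])
        if "remodelling" in kwargs or "remodelling" in data:
            rp = kwargs.get("remodelling", RemodellingParams())
            data.setdefault("remodelling", None)
            data["remodelling"] = rp
        kwargs["scenario"] = _build(ScenarioConfig, data, "scenario")
    cfg = RunConfig(**kwargs)
    if "scenario" not in raw and "remodelling" in kwargs:
        cfg = dataclasses.replace(
            cfg, scenario=dataclasses.replace(cfg.scenario, remodelling=kwargs["remodelling"])
        )
    return cfg


def _asdict(obj):
    d = dataclasses.asdict(obj)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def dump_config(cfg: RunConfig, path=None) -> str:
    """Serialise a RunConfig to YAML (written to ``path`` if given)."""
    data = {"seed": cfg.seed}
    for section in _SECTIONS:
        data[section] = _asdict(getattr(cfg, section))
    sc = _asdict(cfg.scenario)
    sc.pop("remodelling", None)
    data["scenario"] = sc
    text = yaml.safe_dump(data, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def default_config() -> RunConfig:
    return RunConfig()
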