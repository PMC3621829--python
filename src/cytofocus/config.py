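"""Run configuration: YAML in, validated dataclasses out.

A single YAML file (with a versioned ``schema_version`` key) collects
every tunable constant of the pipeline — pixel size, the three filter
thresholds, the HSV stain table, sharpness-feature kernels, scoring
constants, and the workflow loop bounds.  Omitted keys fall back to the
package defaults; unknown keys are rejected by name so typos cannot
silently disable a threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .focus_filters import ColorClassTable, FilterConfig, HSVInterval
from .sharpness import FeatureConfig, ScoreConfig
from .synthetic import DefocusModel, SlideConfig, StainPalette
from .workflow import WorkflowConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid or malformed run configuration."""


@dataclass
class RunConfig:
    """All tunable constants of one reproducible run."""

    schema_version: int = SCHEMA_VERSION
    pixel_size_um: float = 0.46
    seed: int = 0
    filters: FilterConfig = field(default_factory=FilterConfig)
    hsv_table: ColorClassTable = field(default_factory=ColorClassTable)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    scoring: ScoreConfig = field(default_factory=ScoreConfig)
    workflow: WorkflowConfig = field(default_factory=WorkflowConfig)
    slide: SlideConfig = field(default_factory=SlideConfig)


def _coerce(value, target_example):
    if isinstance(target_example, tuple) and isinstance(value, list):
        return tuple(value)
    return value


def _build_dataclass(cls, mapping: dict, section: str):
    if not isinstance(mapping, dict):
        raise ConfigError(f"section '{section}' must be a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    defaults = cls()
    for key, value in mapping.items():
        if key not in names:
            raise ConfigError(f"unknown key '{section}.{key}'")
        current = getattr(defaults, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            kwargs[key] = _build_dataclass(type(current), value, f"{section}.{key}")
        else:
            kwargs[key] = _coerce(value, current)
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid values in section '{section}': {exc}") from exc


def _build_hsv_table(mapping: dict) -> ColorClassTable:
    if not isinstance(mapping, dict):
        raise ConfigError("section 'hsv_table' must be a mapping of classes")
    classes = {}
    for name, spec in mapping.items():
        if not isinstance(spec, dict):
            raise ConfigError(f"hsv_table.{name} must be a mapping")
        allowed = {"hue", "saturation", "value"}
        unknown = set(spec) - allowed
        if unknown:
            raise ConfigError(
                f"unknown key 'hsv_table.{name}.{sorted(unknown)[0]}'")
        if "hue" not in spec:
            raise ConfigError(f"hsv_table.{name} needs a 'hue' interval")
        classes[name] = HSVInterval(
            hue=tuple(spec["hue"]),
            saturation=tuple(spec.get("saturation", (0.0, 1.0))),
            value=tuple(spec.get("value", (0.0, 1.0))),
        )
    return ColorClassTable(classes=classes)


_SECTIONS = {
    "filters": FilterConfig,
    "features": FeatureConfig,
    "scoring": ScoreConfig,
    "workflow": WorkflowConfig,
    "slide": SlideConfig,
}


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, applying defaults for omitted keys.

    Unknown keys are rejected with the offending key named; malformed YAML
    reports the parse location.
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark else ""
        raise ConfigError(f"malformed config{where}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    cfg = RunConfig()
    for key, value in raw.items():
        if key == "schema_version":
            if value != SCHEMA_VERSION:
                raise ConfigError(f"unsupported schema_version {value!r}")
        elif key == "pixel_size_um":
            cfg.pixel_size_um = float(value)
        elif key == "seed":
            cfg.seed = int(value)
        elif key == "hsv_table":
            cfg.hsv_table = _build_hsv_table(value)
        elif key in _SECTIONS:
            setattr(cfg, key, _build_dataclass(_SECTIONS[key], value, key))
        else:
            raise ConfigError(f"unknown key '{key}'")
    return cfg


def dump_config(cfg: RunConfig) -> str:
    """Serialize a RunConfig back to YAML (lossless round-trip)."""

    def plain(value):
        if isinstance(value, tuple):
            return [plain(v) for v in value]
        if isinstance(value, dict):
            return {k: plain(v) for k, v in value.items()}
        if isinstance(value, list):
            return [plain(v) for v in value]
        return value

    def dc(obj):
        return plain(dataclasses.asdict(obj))

    payload = {
        "schema_version": cfg.schema_version,
        "pixel_size_um": cfg.pixel_size_um,
        "seed": cfg.seed,
        "filters": dc(cfg.filters),
        "hsv_table": {
            name: {"hue": list(iv.hue), "saturation": list(iv.saturation),
                   "value": list(iv.value)}
            for name, iv in cfg.hsv_table.classes.items()
        },
        "features": dc(cfg.features),
        "scoring": dc(cfg.scoring),
        "workflow": dc(cfg.workflow),
        "slide": dc(cfg.slide),
    }
    return yaml.safe_dump(payload, sort_keys=False)
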