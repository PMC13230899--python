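"""Pipeline configuration: one YAML file, nested per-stage sections.

``validate_config`` collects every problem (unknown keys, bad types,
violated invariants) instead of failing on the first; ``resolve_config``
applies defaults and returns a fully populated :class:`PipelineConfig`
which is echoed to disk by the pipeline, so a run's exact settings are
always recoverable. Resolution is idempotent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .model import ModelConfig
from .simulate import SimulationConfig
from .train import TrainConfig


@dataclass
class FeatureConfig:
    het_vaf_low: float = 0.02
    het_vaf_high: float = 0.6

    def __post_init__(self):
        if not 0.0 <= self.het_vaf_low < self.het_vaf_high <= 1.0:
            raise ValueError("het VAF window must satisfy 0 <= low < high <= 1")


@dataclass
class EvaluateConfig:
    trend_interval_width: float = 0.1
    residual_bins: int = 30
    figures: bool = True

    def __post_init__(self):
        if self.trend_interval_width <= 0 or self.residual_bins < 1:
            raise ValueError("trend_interval_width and residual_bins must be positive")


@dataclass
class PipelineConfig:
    seed: int = 0
    output_root: str = "snvpurify_run"
    holdout_fraction: float = 0.25
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)

    def __post_init__(self):
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must lie in (0, 1)")


_SECTIONS = {
    "simulation": SimulationConfig,
    "features": FeatureConfig,
    "model": ModelConfig,
    "train": TrainConfig,
    "evaluate": EvaluateConfig,
}
_TOP_LEVEL = {"seed", "output_root", "holdout_fraction", *_SECTIONS}

# tuple-valued fields arrive from YAML as lists
_TUPLE_FIELDS = {"purity_range", "true_count_range", "group_input_dims"}


def _coerce(section_cls, raw: dict) -> tuple[Any, list[str]]:
    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(section_cls)}
    kwargs = {}
    for k, v in raw.items():
        if k not in known:
            errors.append(f"unknown key {k!r} in section {section_cls.__name__}")
            continue
        if k in _TUPLE_FIELDS and isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    if errors:
        return None, errors
    try:
        return section_cls(**kwargs), []
    except (ValueError, TypeError) as exc:
        return None, [f"{section_cls.__name__}: {exc}"]


def validate_config(raw: dict | None) -> tuple[PipelineConfig | None, list[str]]:
    """Resolve a raw config mapping; returns (config or None, error list)."""
    raw = dict(raw or {})
    errors: list[str] = []
    for k in raw:
        if k not in _TOP_LEVEL:
            errors.append(f"unknown top-level key {k!r}")
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {})
        if section is None:
            section = {}
        if not isinstance(section, dict):
            errors.append(f"section {name!r} must be a mapping")
            continue
        obj, errs = _coerce(cls, section)
        errors.extend(errs)
        if obj is not None:
            kwargs[name] = obj
    for k in ("seed", "output_root", "holdout_fraction"):
        if k in raw:
            kwargs[k] = raw[k]
    if errors:
        return None, errors
    try:
        cfg = PipelineConfig(**kwargs)
    except (ValueError, TypeError) as exc:
        return None, [str(exc)]
    # a global seed propagates into stages that kept their default seed
    if "seed" in raw or cfg.seed != 0:
        for section in (cfg.simulation, cfg.model, cfg.train):
            src = raw.get({SimulationConfig: "simulation", ModelConfig: "model",
                           TrainConfig: "train"}[type(section)], {}) or {}
            if "seed" not in src:
                section.seed = cfg.seed
    return cfg, []


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML config file; raises on any error. A missing
    or empty file yields the defaults."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: top level must be a mapping")
    cfg, errors = validate_config(raw)
    if cfg is None:
        raise ValueError(f"invalid configuration: {'; '.join(errors)}")
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Echo a fully resolved config to YAML."""
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def config_to_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for k in _TUPLE_FIELDS:  # YAML round-trips lists, not tuples
        for section in d.values():
            if isinstance(section, dict) and k in section:
                section[k] = list(section[k])
    return d
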