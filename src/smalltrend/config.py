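"""YAML run configuration: schema checking, defaults, lossless round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from smalltrend.model import McmcConfig, ModelSpec
from smalltrend.synthetic import DesignConfig, PopulationConfig, TruthParams


@dataclass
class JoinpointConfig:
    k_max: int = 4
    alpha: float = 0.05
    n_perm: int = 499
    levels: tuple[str, ...] = ("national", "state", "age", "sex", "sex_age")
    detailed: bool = False  # also fit the 112 detailed series


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; seed is mandatory."""

    seed: int
    out_dir: str = "smalltrend_run"
    design: DesignConfig = field(default_factory=DesignConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    truth: TruthParams = field(default_factory=TruthParams)
    model: ModelSpec = field(default_factory=ModelSpec)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    joinpoint: JoinpointConfig = field(default_factory=JoinpointConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "design": DesignConfig,
    "population": PopulationConfig,
    "truth": TruthParams,
    "model": ModelSpec,
    "mcmc": McmcConfig,
    "joinpoint": JoinpointConfig,
}

_LIST_FIELDS = {"survey_years", "zero_sample_domains", "levels"}


def _build_section(cls, payload: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    obj_kwargs = {}
    for key, value in payload.items():
        if key not in allowed:
            raise ValueError(f"unknown configuration key: {path}.{key}")
        if key in _LIST_FIELDS and isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        obj_kwargs[key] = value
    try:
        return cls(**obj_kwargs)
    except TypeError as exc:
        raise ValueError(f"invalid value under {path}: {exc}") from exc


def validate_config(path_or_dict) -> RunConfig:
    """Load and validate a YAML run config.

    Unknown keys are rejected with their full key path; missing sections
    take the defaults, which reproduce the reference setup (7 survey waves,
    3 chains x 10000/5 draws, joinpoint K_max 4).
    """
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict)
    if not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")
    if "seed" not in raw:
        raise ValueError("configuration key 'seed' is mandatory")

    kwargs = {}
    for key, value in raw.items():
        if key == "seed":
            if not isinstance(value, int):
                raise ValueError("seed: expected an integer")
            kwargs["seed"] = value
        elif key == "out_dir":
            kwargs["out_dir"] = str(value)
        elif key in _SECTIONS:
            if not isinstance(value, dict):
                raise ValueError(f"{key}: expected a mapping")
            kwargs[key] = _build_section(_SECTIONS[key], value, key)
        else:
            raise ValueError(f"unknown configuration key: {key}")
    cfg = RunConfig(**kwargs)
    cfg.design.validate()
    cfg.population.validate()
    cfg.truth.validate()
    cfg.model.validate()
    cfg.mcmc.validate()
    if cfg.mcmc.chains == 1:
        import warnings

        warnings.warn("chains=1: R-hat convergence diagnostics will be unavailable", stacklevel=2)
    return cfg
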