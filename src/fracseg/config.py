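"""YAML run configuration: strict parsing into the stage dataclasses.

One file drives the whole pipeline; sections mirror the stage configs
field-for-field.  Unknown keys are rejected with their full path so typos
(``trian:``) fail loudly instead of silently using defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass

import yaml

from .metrics import ToleranceSpec
from .model import UNetSpec
from .phantom import PhantomConfig
from .preprocess import TrainConfig


@dataclass
class StageToggles:
    simulate: bool = True
    train: bool = True
    predict: bool = True
    evaluate: bool = True


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    model: UNetSpec = field(default_factory=UNetSpec)
    eval: ToleranceSpec = field(default_factory=ToleranceSpec)
    stages: StageToggles = field(default_factory=StageToggles)
    output_dir: str = "fracseg_run"
    seed: int = 0

    def __post_init__(self) -> None:
        # one seed drives every stochastic stage unless a section pins its own
        self.phantom.seed = self.phantom.seed or self.seed
        self.train.seed = self.train.seed or self.seed
        if self.model.bottom_dropout_rate != self.train.dropout_rate:
            self.model.bottom_dropout_rate = self.train.dropout_rate
        if self.train.patch_size % 2 ** self.model.depth:
            raise ValueError(
                f"train.patch_size ({self.train.patch_size}) must be divisible "
                f"by 2^model.depth ({2 ** self.model.depth})")


class ConfigError(ValueError):
    pass


def _coerce(value, ftype, path: str):
    origin = getattr(ftype, "__origin__", None)
    if origin is tuple and isinstance(value, (list, tuple)):
        return tuple(value)
    return value


def _build_dataclass(cls, data, path: str = ""):
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ConfigError(f"{path or cls.__name__}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown key {path + key!r}")
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        sub = data[name]
        ftype = f.type if not isinstance(f.type, str) else None
        target = _nested_dataclass(cls, f)
        if target is not None:
            kwargs[name] = _build_dataclass(target, sub, f"{path}{name}.")
        else:
            kwargs[name] = _coerce(sub, ftype, f"{path}{name}")
            if isinstance(kwargs[name], list):
                kwargs[name] = tuple(kwargs[name])
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{path.rstrip('.') or cls.__name__}: {exc}") from exc


def _nested_dataclass(cls, f):
    """Resolve a field's dataclass type from its default factory (robust
    against stringified annotations under `from __future__ import annotations`)."""
    if f.default_factory is not dataclasses.MISSING and is_dataclass(f.default_factory):
        return f.default_factory
    if f.default is not dataclasses.MISSING and is_dataclass(type(f.default)):
        return type(f.default)
    return None


def validate_config(path) -> RunConfig:
    """Parse and fully validate a YAML run configuration.

    Defaults fill any omitted field; every violation is reported with its
    field path; unknown keys are rejected.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return build_run_config(raw or {})


def build_run_config(raw: dict) -> RunConfig:
    return _build_dataclass(RunConfig, raw)


def config_to_dict(cfg) -> dict:
    """Recursive dataclass -> plain-dict (for run manifests and echo)."""
    if is_dataclass(cfg):
        return {f.name: config_to_dict(getattr(cfg, f.name)) for f in fields(cfg)}
    if isinstance(cfg, (list, tuple)):
        return [config_to_dict(v) for v in cfg]
    return cfg
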