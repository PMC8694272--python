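"""Run configuration: one YAML file drives the whole pipeline.

The file has four stage sections (``phantom``, ``cae``, ``gan``,
``eval``) plus global keys (``seed``, ``output_dir``, dataset sizes).
Every stage derives its randomness from the global seed so a run is a
pure function of its configuration. Serialization round-trips
losslessly (missing keys fall back to defaults; unknown keys are an
error so typos cannot silently change a run).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .adversarial import GANConfig, LossWeights
from .cae import CAEConfig
from .exceptions import ConfigurationError
from .phantom import PhantomParams
from .presets import desk_gan_config

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class EvalConfig:
    threshold: float = 0.5


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "runs/fspet"
    n_train: int = 200
    n_val: int = 0
    n_test: int = 50
    phantom: PhantomParams = field(default_factory=PhantomParams)
    cae: CAEConfig = field(default_factory=CAEConfig)
    gan: GANConfig = field(default_factory=desk_gan_config)
    eval: EvalConfig = field(default_factory=EvalConfig)

    def __post_init__(self):
        # stage seeds follow the global seed unless explicitly overridden
        self.phantom = dataclasses.replace(self.phantom, seed=self.seed)
        self.cae.seed = self.seed
        self.gan.seed = self.seed

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed, "output_dir": self.output_dir,
            "n_train": self.n_train, "n_val": self.n_val,
            "n_test": self.n_test,
            "phantom": dataclasses.asdict(self.phantom),
            "cae": {k: v for k, v in dataclasses.asdict(self.cae).items()
                    if k != "dtype"},
            "gan": {k: v for k, v in dataclasses.asdict(self.gan).items()
                    if k != "dtype"},
            "eval": dataclasses.asdict(self.eval),
        }
        d["phantom"]["brain_axes"] = (
            list(self.phantom.brain_axes)
            if self.phantom.brain_axes is not None else None)
        return d


_SECTIONS = {"phantom": PhantomParams, "cae": CAEConfig, "gan": GANConfig,
             "eval": EvalConfig}
_GLOBALS = ("seed", "output_dir", "n_train", "n_val", "n_test")


def _build_section(name: str, cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)} - {"dtype"}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in section {name!r}")
    data = dict(data)
    if name == "gan" and "weights" in data:
        data["weights"] = LossWeights(**data["weights"])
    if name == "phantom" and data.get("brain_axes") is not None:
        data["brain_axes"] = tuple(data["brain_axes"])
    if name == "gan":
        # overrides apply on top of the desk preset, keeping YAML runs
        # consistent with the RunConfig default
        return dataclasses.replace(desk_gan_config(), **data)
    return cls(**data)


def config_from_dict(data: dict) -> RunConfig:
    unknown = set(data) - set(_GLOBALS) - set(_SECTIONS)
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs = {k: data[k] for k in _GLOBALS if k in data}
    for name, cls in _SECTIONS.items():
        if name in data:
            if not isinstance(data[name], dict):
                raise ConfigurationError(f"section {name!r} must be a mapping")
            kwargs[name] = _build_section(name, cls, data[name])
    return RunConfig(**kwargs)


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config {path!r} is not a YAML mapping")
    return config_from_dict(data)


def save_config(config: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
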