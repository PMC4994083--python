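"""Run configuration: a flat YAML/JSON key-value document.

A configuration fully defines a run: model parameters (N, M, M_cons, R_Max,
w, nu), the generation schedule, the initialisation mode and the master
seed.  Unknown keys are an error so typos do not silently fall back to
defaults.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .core import ModelParams
from .errors import ConfigurationError, InvalidParameterError

__all__ = ["RunConfig", "load_config", "save_config"]

_REQUIRED = (
    "community_size",
    "num_resources",
    "num_consumed",
    "r_max",
    "selection_intensity",
    "mutation_prob",
)

_DEFAULTS = {
    "frequency_dependent": True,
    "generations": 10_000,
    "burn_in": 0,
    "sampling_interval": 1,
    "init_mode": "single",
    "master_seed": 0,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a single simulation run."""

    community_size: int
    num_resources: int
    num_consumed: int
    r_max: float
    selection_intensity: float
    mutation_prob: float
    frequency_dependent: bool = True
    generations: int = 10_000
    burn_in: int = 0
    sampling_interval: int = 1
    init_mode: str = "single"  # "single" or "k_species:<k>"
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.model_params()  # delegates the model-parameter invariants
        if self.generations < 0:
            raise ConfigurationError("generations must be >= 0")
        if self.generations > 0 and not (0 <= self.burn_in < self.generations):
            raise ConfigurationError("require 0 <= burn_in < generations")
        if self.generations == 0 and self.burn_in != 0:
            raise ConfigurationError("burn_in must be 0 when generations is 0")
        if self.sampling_interval < 1:
            raise ConfigurationError("sampling_interval must be >= 1")
        if self.master_seed < 0:
            raise ConfigurationError("master_seed must be a non-negative integer")
        self.init_spec()

    def model_params(self) -> ModelParams:
        try:
            return ModelParams(
                community_size=self.community_size,
                num_resources=self.num_resources,
                num_consumed=self.num_consumed,
                r_max=self.r_max,
                selection_intensity=self.selection_intensity,
                mutation_prob=self.mutation_prob,
                frequency_dependent=self.frequency_dependent,
            )
        except InvalidParameterError as exc:
            raise ConfigurationError(str(exc)) from exc

    def init_spec(self) -> tuple[str, int]:
        """Parse init_mode into (mode, k)."""
        if self.init_mode == "single":
            return "single", 1
        if self.init_mode.startswith("k_species"):
            _, _, tail = self.init_mode.partition(":")
            try:
                k = int(tail) if tail else 10
            except ValueError:
                raise ConfigurationError(
                    f"bad init_mode {self.init_mode!r}: expected k_species:<int>"
                ) from None
            if k < 1:
                raise ConfigurationError("init_mode k_species needs k >= 1")
            return "k_species", k
        raise ConfigurationError(f"unknown init_mode: {self.init_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a flat YAML (or JSON) configuration file."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path} must contain a flat key-value mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s): {', '.join(sorted(unknown))}"
        )
    missing = [k for k in _REQUIRED if k not in data]
    if missing:
        raise ConfigurationError(
            f"missing required configuration key(s): {', '.join(missing)}"
        )
    return RunConfig(**{**_DEFAULTS, **data})


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration back out (YAML for .yaml/.yml, else JSON)."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    else:
        path.write_text(json.dumps(config.to_dict(), indent=2) + "\n")
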