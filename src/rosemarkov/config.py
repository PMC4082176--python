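"""Scenario configuration: parameter sets plus run settings, loadable from
YAML or JSON and overridable from the command line."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .parameters import (
    HONG_KONG_2012,
    HONG_KONG_INITIAL_ILL,
    HONG_KONG_Q0,
    PARAM_NAMES,
    ParameterError,
    TransitionParameters,
)


class ConfigError(ValueError):
    """A configuration file or override is malformed or inconsistent."""


_KNOWN_KEYS = set(PARAM_NAMES) | {
    "Q0",
    "initial_ill",
    "reference_dp41",
    "tol",
    "max_years",
    "sim_years",
    "burn_in",
    "seed",
}


@dataclass(frozen=True)
class ScenarioConfig:
    """One fully specified analysis scenario.

    Defaults reproduce the Hong Kong 2012 setting: the six estimated
    transition probabilities, Q0 = 7 million, 150,000 prevalent mentally
    ill, and a reference intervention of 1 per 100,000 on p41.
    """

    params: TransitionParameters = HONG_KONG_2012
    Q0: float = HONG_KONG_Q0
    #: None means "the Hong Kong prevalent stock scaled to Q0"
    initial_ill: float | None = None
    reference_dp41: float = 1e-5
    tol: float = 1e-10
    max_years: int = 100_000
    sim_years: int = 200
    burn_in: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        try:
            self.params.validate()
        except ParameterError as exc:
            raise ConfigError(str(exc)) from exc
        if self.Q0 <= 0:
            raise ConfigError("Q0: must be positive")
        if self.initial_ill is not None and not (0 <= self.initial_ill <= self.Q0):
            raise ConfigError("initial_ill: must lie in [0, Q0]")
        if self.reference_dp41 <= 0:
            raise ConfigError("reference_dp41: must be positive")
        if self.tol <= 0:
            raise ConfigError("tol: must be positive")

    @property
    def resolved_initial_ill(self) -> float:
        """The starting mentally ill stock, scaled to Q0 when unset."""
        if self.initial_ill is not None:
            return self.initial_ill
        return self.Q0 * HONG_KONG_INITIAL_ILL / HONG_KONG_Q0

    def as_dict(self) -> dict:
        d = self.params.as_dict()
        d.update(
            Q0=self.Q0,
            initial_ill=self.resolved_initial_ill,
            reference_dp41=self.reference_dp41,
            tol=self.tol,
            max_years=self.max_years,
            sim_years=self.sim_years,
            burn_in=self.burn_in,
            seed=self.seed,
        )
        return d

    def digest(self) -> str:
        """Stable hash of the scenario, recorded in run logs."""
        canon = json.dumps(self.as_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def with_overrides(self, **overrides) -> "ScenarioConfig":
        """A copy with non-None overrides applied (CLI flags win over file)."""
        changes = {k: v for k, v in overrides.items() if v is not None}
        if not changes:
            return self
        param_changes = {k: changes.pop(k) for k in list(changes) if k in PARAM_NAMES}
        params = self.params.replace(**param_changes) if param_changes else self.params
        try:
            return dataclasses.replace(self, params=params, **changes)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        """Load a scenario from YAML or JSON (flat keys: the six p_ij plus
        Q0, initial_ill, reference_dp41, tol, max_years, sim_years,
        burn_in, seed; missing keys take the defaults)."""
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping of keys to values")
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        param_values = {k: float(raw[k]) for k in PARAM_NAMES if k in raw}
        try:
            params = HONG_KONG_2012.replace(**param_values)
        except ParameterError as exc:
            raise ConfigError(str(exc)) from exc
        rest = {k: v for k, v in raw.items() if k not in PARAM_NAMES}
        ints = {"max_years", "sim_years", "burn_in", "seed"}
        kwargs = {k: (int(v) if k in ints else float(v)) for k, v in rest.items()}
        return cls(params=params, **kwargs)
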