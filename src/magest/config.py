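"""Experiment configuration: YAML/JSON files with validated defaults.

A config fully determines a run.  Defaults reproduce the reference
subsecond-timing regime: drifts ``A_m = A_r = 0.25`` per ms, measurement
noise ``sigma_m = 1``, reproduction noise ``sigma_r = 0.5``, Euler step
5 ms, eleven evenly spaced stimuli per range, 50 burn-in trials.  When
``memory_weight`` is omitted it is resolved per range to the
error-minimizing weight (clamped to the grid-search optimum if the closed
form falls outside (0, 1]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .analytics import StimulusSet
from .model import ModelParams
from .optimality import a_min_closed_form, grid_search_a

__all__ = ["ConfigError", "ExperimentConfig", "load_config"]


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the field."""


_PARAM_FIELDS = (
    "drift_measure",
    "noise_measure",
    "drift_reproduce",
    "noise_reproduce",
    "memory_weight",
    "dt",
)

_DEFAULTS = {
    "drift_measure": 0.25,
    "noise_measure": 1.0,
    "drift_reproduce": 0.25,
    "noise_reproduce": 0.5,
    "memory_weight": None,  # resolved per range to the optimal weight
    "dt": 5.0,
    "k": 11,
    "n_trials": 10_000,
    "burn_in": 50,
    "mode": "exact",
    "output_dir": ".",
}


@dataclass
class ExperimentConfig:
    ranges: list[tuple[float, float]]
    seed: int
    drift_measure: float = 0.25
    noise_measure: float = 1.0
    drift_reproduce: float = 0.25
    noise_reproduce: float = 0.5
    memory_weight: float | None = None
    dt: float = 5.0
    k: int = 11
    n_trials: int = 10_000
    burn_in: int = 50
    mode: str = "exact"
    output_dir: str = "."

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ConfigError("ranges: must be non-empty")
        try:
            self.ranges = [(float(lo), float(hi)) for lo, hi in self.ranges]
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"ranges: expected pairs of numbers ({exc})") from exc
        for lo, hi in self.ranges:
            if not 0 < lo < hi:
                raise ConfigError(f"ranges: need 0 < min < max, got ({lo}, {hi})")
        if self.memory_weight is not None and not 0 < self.memory_weight <= 1:
            raise ConfigError("memory_weight: must lie in (0, 1]; 0 is excluded")
        if self.k < 2:
            raise ConfigError("k: must be >= 2")
        if self.n_trials <= self.burn_in:
            raise ConfigError("n_trials: must exceed burn_in")
        if self.burn_in < 0:
            raise ConfigError("burn_in: must be >= 0")
        if self.mode not in ("exact", "path"):
            raise ConfigError("mode: must be 'exact' or 'path'")
        # delegate numeric parameter validation, with a placeholder weight
        try:
            self.params_for_weight(1.0)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    def stimulus_sets(self) -> list[StimulusSet]:
        return [StimulusSet.from_range(lo, hi, self.k) for lo, hi in self.ranges]

    def params_for_weight(self, weight: float) -> ModelParams:
        return ModelParams(
            drift_measure=self.drift_measure,
            noise_measure=self.noise_measure,
            drift_reproduce=self.drift_reproduce,
            noise_reproduce=self.noise_reproduce,
            memory_weight=weight,
            dt=self.dt,
        )

    def resolve_weight(self, stim_set: StimulusSet) -> float:
        """Configured weight, or the error-minimizing weight for this range."""
        if self.memory_weight is not None:
            return self.memory_weight
        probe = self.params_for_weight(1.0)
        closed = a_min_closed_form(probe, stim_set)
        if 0 < closed <= 1:
            return closed
        return grid_search_a(probe, stim_set, grid_step=1e-3)

    def params_for(self, stim_set: StimulusSet) -> ModelParams:
        return self.params_for_weight(self.resolve_weight(stim_set))

    def to_manifest(self) -> dict:
        return {
            "ranges": [list(r) for r in self.ranges],
            "seed": self.seed,
            **{name: getattr(self, name) for name in _PARAM_FIELDS},
            "k": self.k,
            "n_trials": self.n_trials,
            "burn_in": self.burn_in,
            "mode": self.mode,
            "output_dir": self.output_dir,
        }


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate a YAML or JSON config file.

    JSON being a YAML subset, both formats are accepted by the same
    parser.  Unknown keys are rejected to keep every free choice explicit.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    known = set(_DEFAULTS) | {"ranges", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown field(s): {', '.join(sorted(unknown))}")
    for required in ("ranges", "seed"):
        if required not in raw:
            raise ConfigError(f"{required}: required field is missing")
    merged = {**_DEFAULTS, **raw}
    return ExperimentConfig(**merged)


def write_manifest(config: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_manifest(), indent=2))
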