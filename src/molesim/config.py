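"""Configuration parsing: YAML files and flag overrides -> ExperimentConfig.

Unspecified fields take the model's standard values (quality 0.75, delta
0.10, no bias/handicap/asymmetry, stream of 10,000, sample of 6).
Unknown keys and out-of-range values are rejected with the offending key
named, so a typo in a config file fails loudly instead of silently
running the defaults.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError
from .experiments import SCENARIO_1, SCENARIO_2, ExperimentConfig
from .population import ScenarioSpec

__all__ = ["parse_config", "KNOWN_KEYS"]

_GRID_KEYS = (
    "quality_grid",
    "delta_grid",
    "theta_grid",
    "handicap_grid",
    "p_grid",
    "asymmetry_grid",
)

KNOWN_KEYS = frozenset(
    {
        "experiment",
        "scenario",
        "runs",
        "seed",
        "quality",
        "delta",
        "sensitivity_bias",
        "handicap",
        "asymmetry",
        "sample_size",
        "stream_size",
        *_GRID_KEYS,
    }
)

_RANGES: dict[str, tuple[float, float]] = {
    "quality": (0.0, 1.0),
    "delta": (0.0, 1.0),
    "sensitivity_bias": (-1.0, 1.0),
    "handicap": (0.0, 1.0),
    "asymmetry": (-1.0, 1.0),
}


def _resolve_scenarios(value: Any) -> tuple[ScenarioSpec, ...]:
    if value in (None, "both", "Both"):
        return (SCENARIO_1, SCENARIO_2)
    if value in (1, "1", "uniform"):
        return (SCENARIO_1,)
    if value in (2, "2", "gaussian"):
        return (SCENARIO_2,)
    raise ConfigurationError(
        f"scenario: expected 1, 2, 'uniform', 'gaussian' or 'both', got {value!r}"
    )


def _check_range(key: str, value: float) -> float:
    lo, hi = _RANGES[key]
    try:
        value = float(value)
    except (TypeError, ValueError):
        raise ConfigurationError(f"{key}: expected a number, got {value!r}") from None
    if not lo <= value <= hi:
        raise ConfigurationError(f"{key}: value {value} outside [{lo}, {hi}]")
    return value


def _check_grid(key: str, values: Any) -> tuple[float, ...]:
    try:
        grid = tuple(float(v) for v in values)
    except (TypeError, ValueError):
        raise ConfigurationError(f"{key}: expected a sequence of numbers") from None
    if not grid:
        raise ConfigurationError(f"{key}: grid must not be empty")
    return grid


def parse_config(path: str | Path | None = None, **overrides: Any) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML file and/or overrides.

    ``overrides`` use the same keys as the file and win over it; a value
    of ``None`` in the overrides means "not given".
    """
    raw: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ConfigurationError(f"config file {path} must contain a key-value mapping")
        raw.update(loaded)
    raw.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(raw) - KNOWN_KEYS
    if unknown:
        raise ConfigurationError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")

    kwargs: dict[str, Any] = {}
    if "experiment" in raw:
        kwargs["experiment_id"] = int(raw["experiment"])
    kwargs["scenarios"] = _resolve_scenarios(raw.get("scenario"))
    if "runs" in raw:
        kwargs["runs_per_setting"] = int(raw["runs"])
    if "seed" in raw:
        kwargs["master_seed"] = int(raw["seed"])
    for key in ("sample_size", "stream_size"):
        if key in raw:
            kwargs[key] = int(raw[key])
    for key in _RANGES:
        if key in raw:
            kwargs[key] = _check_range(key, raw[key])
    for key in _GRID_KEYS:
        if key in raw:
            kwargs[key] = _check_grid(key, raw[key])
    return ExperimentConfig(**kwargs)
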