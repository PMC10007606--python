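"""Result serialization: sweep CSVs, alarm-tally JSON, and run manifests.

Every output file is accompanied by a run manifest recording the full
parameter grids, scenario, run counts, master seed, RNG and tool
version — enough to reproduce the file bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from . import __version__
from .errors import DomainError
from .experiments import AlarmConfig, AlarmTally, ExperimentConfig, SWEEP_COLUMNS

__all__ = [
    "RunManifest",
    "write_sweep_csv",
    "write_alarm_json",
    "read_alarm_json",
    "manifest_path_for",
]

_RNG_DESCRIPTION = "numpy PCG64 via SeedSequence([master_seed, experiment_id, scenario, cell])"


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce one output table bit-identically."""

    experiment_id: int
    scenarios: tuple[str, ...]
    runs_per_setting: int
    sample_size: int
    stream_size: int
    master_seed: int
    parameters: dict[str, float]
    grids: dict[str, tuple[float, ...]]
    tool_version: str = __version__
    rng: str = _RNG_DESCRIPTION
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )
    extras: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_config(
        cls,
        config: ExperimentConfig,
        grids: Mapping[str, Sequence[float]] | None = None,
        **extras: Any,
    ) -> "RunManifest":
        return cls(
            experiment_id=config.experiment_id,
            scenarios=tuple(s.label for s in config.scenarios),
            runs_per_setting=config.runs,
            sample_size=config.sample_size,
            stream_size=config.stream_size,
            master_seed=config.master_seed,
            parameters={
                "quality": config.quality,
                "delta": config.delta,
                "sensitivity_bias": config.sensitivity_bias,
                "handicap": config.handicap,
                "asymmetry": config.asymmetry,
            },
            grids={k: tuple(v) for k, v in (grids or {}).items()},
            extras=dict(extras),
        )

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def manifest_path_for(path: str | Path) -> Path:
    return Path(str(path) + ".manifest.json")


def _write_manifest(manifest: RunManifest | None, path: str | Path) -> None:
    if manifest is None:
        return
    manifest_path_for(path).write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True) + "\n"
    )


def write_sweep_csv(
    result: pd.DataFrame, path: str | Path, manifest: RunManifest | None = None
) -> Path:
    """Write a sweep table: fixed column order, 6-decimal floats, blanks for NaN.

    Row order is the drivers' deterministic grid order and is preserved, so
    the same configuration and master seed always produce byte-identical
    files.  A ``<path>.manifest.json`` sidecar is written when a manifest
    is supplied.
    """
    if result.empty:
        raise DomainError("refusing to write an empty sweep table")
    path = Path(path)
    result.loc[:, SWEEP_COLUMNS].to_csv(
        path, index=False, float_format="%.6f", na_rep="", lineterminator="\n"
    )
    _write_manifest(manifest, path)
    return path


def write_alarm_json(
    results: Mapping[str, Mapping[str, AlarmTally]],
    cases: Sequence[AlarmConfig],
    manifest: RunManifest | None,
    path: str | Path,
) -> Path:
    """Write catastrophe-alarm tallies (counts and proportions) with the manifest."""
    payload: dict[str, Any] = {
        "manifest": manifest.to_dict() if manifest is not None else None,
        "cases": [],
    }
    for case in cases:
        per_alg = results[case.label]
        payload["cases"].append(
            {
                "label": case.label,
                "catastrophe_threshold": case.catastrophe_threshold,
                "alarm_threshold": case.alarm_threshold,
                "sample_sizes": list(case.sample_sizes),
                "algorithms": {
                    name: {
                        "counts": {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn},
                        "proportions": t.proportions(),
                    }
                    for name, t in per_alg.items()
                },
            }
        )
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_alarm_json(path: str | Path) -> tuple[dict[str, Any] | None, dict[str, dict[str, AlarmTally]]]:
    """Reload an alarm-tally file into (manifest dict, {case label: {algorithm: tally}})."""
    payload = json.loads(Path(path).read_text())
    results: dict[str, dict[str, AlarmTally]] = {}
    for case in payload["cases"]:
        results[case["label"]] = {
            name: AlarmTally(**entry["counts"])
            for name, entry in case["algorithms"].items()
        }
    return payload.get("manifest"), results
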