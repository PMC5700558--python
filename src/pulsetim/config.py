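"""Configuration loading, validation, and result serialization.

A scenario is described by a single YAML or JSON file::

    params: {preset: table2, beta: 0.1}      # or all ten parameters
    schedule: {d_cd4: 10, d_il4: 0, tau: 7}
    initial_conditions: [[0.5, 0.01, 0]]
    horizon: 140
    policy: {rtol: 1.0e-9, atol: 1.0e-12, transient_cycles: 2000}
    sweep: {parameter: d_il4, grid: [70, 80, 90], bracket: [70, 90]}
    grid2d: {x: {parameter: d_cd4, range: [0, 100]},
             y: {parameter: d_il4, range: [0, 100]}, coarse: 17, depth: 5}
    output: {directory: out, format: csv}

Unknown keys are rejected with the offending key named.  Every run
writes a manifest (config hash, package version, resolved numeric
policy) next to its outputs so results are traceable to their inputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .impulsive import DoseSchedule, NumericPolicy, Trajectory
from .model import ModelParams, preset

__all__ = ["ScenarioConfig", "ConfigError", "load_config", "write_results", "make_manifest"]


class ConfigError(ValueError):
    """A configuration problem, naming the offending key."""


_TOP_KEYS = {"params", "schedule", "initial_conditions", "horizon", "policy", "sweep", "grid2d", "output"}
_POLICY_KEYS = {f.name for f in dataclasses.fields(NumericPolicy)}
_SCHEDULE_KEYS = {"d_cd4", "d_il4", "tau"}


@dataclass(frozen=True)
class ScenarioConfig:
    """A fully validated scenario: parameters, dosing, runs, numerics."""

    params: ModelParams
    schedule: DoseSchedule
    initial_conditions: tuple[tuple[float, float, float], ...]
    horizon: float
    policy: NumericPolicy
    sweep: dict | None = None
    grid2d: dict | None = None
    output: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict, compare=False)


def _reject_unknown(mapping: dict, allowed: set[str], where: str, example: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {where}; allowed keys are "
            f"{sorted(allowed)} (example: {example})"
        )


def _parse_params(node) -> ModelParams:
    if node is None:
        raise ConfigError("missing 'params'; example: params: {preset: table2, beta: 0.1}")
    if not isinstance(node, dict):
        raise ConfigError(f"'params' must be a mapping, got {type(node).__name__}")
    node = dict(node)
    if "preset" in node:
        name = node.pop("preset")
        if "beta" not in node:
            raise ConfigError(
                "preset params need 'beta' (tumor antigenicity); "
                "example: params: {preset: table2, beta: 0.1}"
            )
        beta = float(node.pop("beta"))
        try:
            return preset(name, beta, **{k: float(v) for k, v in node.items()})
        except ValueError as exc:
            raise ConfigError(str(exc)) from None
    try:
        return ModelParams.from_dict({k: float(v) for k, v in node.items()})
    except ValueError as exc:
        raise ConfigError(str(exc)) from None


def _parse_schedule(node) -> DoseSchedule:
    if node is None:
        return DoseSchedule()
    _reject_unknown(node, _SCHEDULE_KEYS, "'schedule'", "schedule: {d_cd4: 10, d_il4: 0, tau: 7}")
    try:
        return DoseSchedule(**{k: float(v) for k, v in node.items()})
    except ValueError as exc:
        raise ConfigError(str(exc)) from None


def parse_config(data: dict) -> ScenarioConfig:
    """Validate a config mapping into a :class:`ScenarioConfig`."""
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    _reject_unknown(data, _TOP_KEYS, "config root", "params: {preset: table2, beta: 0.1}")
    params = _parse_params(data.get("params"))
    schedule = _parse_schedule(data.get("schedule"))
    inits_node = data.get("initial_conditions", [[0.1, 0.01, 0.0]])
    inits = []
    for item in inits_node:
        vals = [float(v) for v in item]
        if len(vals) != 3:
            raise ConfigError(
                f"each initial condition needs three components [x, y, z], got {item!r}"
            )
        if any(v < 0 for v in vals):
            raise ConfigError(f"initial condition components must be nonnegative, got {item!r}")
        inits.append(tuple(vals))
    horizon = float(data.get("horizon", 70.0))
    if horizon <= 0:
        raise ConfigError(f"'horizon' must be positive, got {horizon}")
    pol_node = data.get("policy") or {}
    _reject_unknown(pol_node, _POLICY_KEYS, "'policy'", "policy: {rtol: 1.0e-9, transient_cycles: 2000}")
    policy = NumericPolicy(**pol_node)
    return ScenarioConfig(
        params=params,
        schedule=schedule,
        initial_conditions=tuple(inits),
        horizon=horizon,
        policy=policy,
        sweep=data.get("sweep"),
        grid2d=data.get("grid2d"),
        output=data.get("output") or {},
        raw=data,
    )


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML or JSON scenario file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    text = path.read_text()
    if path.suffix in (".json",):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return parse_config(data)


def make_manifest(config: ScenarioConfig) -> dict:
    """Run manifest: config hash, package version, resolved numerics."""
    canonical = json.dumps(config.raw, sort_keys=True, default=float)
    return {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "pulsetim_version": __version__,
        "params": config.params.to_dict(),
        "schedule": dataclasses.asdict(config.schedule),
        "policy": dataclasses.asdict(config.policy),
    }


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return _jsonable(obj.item())
    if isinstance(obj, float) and not np.isfinite(obj):
        return None  # strict JSON has no NaN/Inf; masked mesh points serialize as null
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, complex):
        return {"re": obj.real, "im": obj.imag}
    return obj


def write_results(result, fmt: str, path: str | Path, manifest: dict | None = None) -> Path:
    """Serialize a result to CSV (tabular) or JSON (structured).

    Trajectories become CSV with columns t, x, y, z, pulse_flag (full
    float precision); any dataclass/dict/array structure becomes sorted
    JSON.  A manifest, when given, is written as ``<path>.manifest.json``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        if isinstance(result, Trajectory):
            frame = result.to_frame()
        else:
            import pandas as pd

            frame = result if hasattr(result, "to_csv") else pd.DataFrame(result)
        frame.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "json":
        path.write_text(json.dumps(_jsonable(result), sort_keys=True, indent=1) + "\n")
    else:
        raise ConfigError(f"unknown output format {fmt!r}; use 'csv' or 'json'")
    if manifest is not None:
        Path(str(path) + ".manifest.json").write_text(
            json.dumps(_jsonable(manifest), sort_keys=True, indent=1) + "\n"
        )
    return path
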