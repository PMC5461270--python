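"""Run configuration: validated YAML loading, hashing and result output.

A run configuration bundles the model parameters with the protocol and
output settings.  Serialization is deterministic: JSON with sorted keys
and repr-exact floats (lossless round trip), CSV tables with fixed float
formatting.  The configuration hash is stable under key reordering, so a
hash plus the package version pins every output byte of a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import ModelParameters

__all__ = [
    "ProtocolConfig", "OutputConfig", "RunConfig",
    "load_config", "config_hash", "write_results", "write_json", "read_json",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Settings of the direction-change evaluation protocol."""

    target_speed: float = 2.0      # commanded lateral speed [m/s]
    t_start: float = 1.5           # first switch time of the grid [s]
    spacing: float = 0.03          # grid spacing [s]
    n_trials: int = 101            # grid size
    timeout: float = 15.0          # post-switch cap [s]
    debounce: float = 0.02         # gait-event debounce [s]

    def __post_init__(self) -> None:
        if self.target_speed <= 0:
            raise ValueError("target_speed must be positive")
        if self.t_start <= 0 or self.spacing <= 0 or self.timeout <= 0:
            raise ValueError("t_start, spacing and timeout must be positive")
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        if self.debounce < 0:
            raise ValueError("debounce must be >= 0")


@dataclass(frozen=True)
class OutputConfig:
    """Output paths and formats."""

    out_dir: str = "results"
    log_every: int = 100           # decimation in integrator steps
    formats: tuple[str, ...] = ("csv", "json")

    def __post_init__(self) -> None:
        if self.log_every < 1:
            raise ValueError("log_every must be >= 1")
        bad = set(self.formats) - {"csv", "json", "hdf5"}
        if bad:
            raise ValueError(f"unknown output formats: {sorted(bad)}")


@dataclass(frozen=True)
class RunConfig:
    model: ModelParameters = field(default_factory=ModelParameters)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    output: OutputConfig = field(default_factory=OutputConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output"]["formats"] = list(self.output.formats)
        return d


_SECTIONS = {"model": ModelParameters, "protocol": ProtocolConfig, "output": OutputConfig}


def _build_section(cls, data: dict, errors: list[str], section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    for key in sorted(unknown):
        errors.append(f"{section}: unknown key {key!r}")
    kwargs = {k: v for k, v in data.items() if k in known}
    if section == "output" and "formats" in kwargs:
        kwargs["formats"] = tuple(kwargs["formats"])
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        errors.append(f"{section}: {exc}")
        return None


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing keys take their documented defaults; unknown keys and invalid
    values are rejected with an itemized error list naming each offender.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    errors: list[str] = []
    for key in sorted(set(raw) - set(_SECTIONS)):
        errors.append(f"top level: unknown section {key!r}")
    sections = {}
    for name, cls in _SECTIONS.items():
        data = raw.get(name, {})
        if not isinstance(data, dict):
            errors.append(f"{name}: must be a mapping")
            continue
        built = _build_section(cls, data, errors, name)
        if built is not None:
            sections[name] = built
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(**sections)


def config_hash(config: RunConfig) -> str:
    """SHA-256 of the canonical (sorted-key) JSON form of the config."""
    canonical = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if hasattr(obj, "item"):  # numpy scalar
        return _jsonable(obj.item())
    return obj


def write_json(obj, path) -> None:
    """Deterministic JSON output: sorted keys, repr-exact floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, sort_keys=True, indent=1)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_results(records: list[dict], path_stem, formats=("csv", "json")) -> list[Path]:
    """Write a list of records as deterministic CSV and/or JSON tables.

    Column order is the sorted union of keys, so two runs of the same
    configuration produce identical bytes.  An empty record list yields a
    valid header-only CSV / empty JSON array.
    """
    import pandas as pd

    path_stem = Path(path_stem)
    path_stem.parent.mkdir(parents=True, exist_ok=True)
    columns = sorted({k for rec in records for k in rec})
    written = []
    if "csv" in formats:
        frame = pd.DataFrame(records, columns=columns)
        csv_path = path_stem.with_suffix(".csv")
        with open(csv_path, "w") as fh:
            frame.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")
        written.append(csv_path)
    if "json" in formats:
        json_path = path_stem.with_suffix(".json")
        write_json([{k: rec.get(k) for k in columns} for rec in records], json_path)
        written.append(json_path)
    return written
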