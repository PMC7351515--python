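"""Run configuration: defaults, file loading, validation.

Configs are TOML (preferred, comments allowed) or JSON.  An empty file
yields the full default configuration — the constants of the modelled
rat EDL muscle (28.7 mm, 3 x 16 element topology, the published
constitutive constants, 2 mm imposed displacements, the stated link
stiffnesses).  Unknown keys, type mismatches and out-of-range values are
all collected and reported together.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .fem import SolverParams
from .geometry import GeometryParams, LinkParams
from .materials import AponeurosisParams, EcmParams, FiberParams, MaterialParams
from .scenarios import ScenarioSpec

__all__ = ["ConfigError", "RunConfig", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Invalid configuration; the message lists every problem found."""


@dataclass
class RunConfig:
    geometry: GeometryParams = field(default_factory=GeometryParams)
    materials: MaterialParams = field(default_factory=MaterialParams)
    links: LinkParams = field(default_factory=LinkParams)
    solver: SolverParams = field(default_factory=SolverParams)
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    output_dir: str = "myofem_out"
    seed: int = 0

    def validate(self) -> list[str]:
        return (
            self.geometry.validate()
            + self.materials.validate()
            + self.links.validate()
            + self.solver.validate()
            + self.scenario.validate()
        )


_TUPLE_FIELDS = {"contour_top", "contour_bottom"}


def _apply(obj, data: dict, prefix: str, problems: list[str]):
    names = {f.name: f for f in dataclasses.fields(obj)}
    for key, val in data.items():
        if key not in names:
            problems.append(f"unknown key {prefix}{key}")
            continue
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(val, dict):
            _apply(current, val, f"{prefix}{key}.", problems)
        elif isinstance(val, dict):
            problems.append(f"{prefix}{key}: expected a value, got a table")
        elif key in _TUPLE_FIELDS:
            try:
                setattr(obj, key, tuple((float(t), float(y)) for t, y in val))
            except (TypeError, ValueError):
                problems.append(f"{prefix}{key}: expected a list of (t, y) pairs")
        elif isinstance(current, bool):
            if not isinstance(val, bool):
                problems.append(f"{prefix}{key}: expected a boolean")
            else:
                setattr(obj, key, val)
        elif isinstance(current, int) and not isinstance(current, bool):
            if isinstance(val, bool) or not isinstance(val, (int, float)):
                problems.append(f"{prefix}{key}: expected an integer")
            elif isinstance(val, float) and not val.is_integer():
                problems.append(f"{prefix}{key}: expected an integer")
            else:
                setattr(obj, key, int(val))
        elif isinstance(current, float):
            if isinstance(val, bool) or not isinstance(val, (int, float)):
                problems.append(f"{prefix}{key}: expected a number")
            else:
                setattr(obj, key, float(val))
        elif isinstance(current, str):
            if not isinstance(val, str):
                problems.append(f"{prefix}{key}: expected a string")
            else:
                setattr(obj, key, val)
        else:
            setattr(obj, key, val)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a TOML/JSON config merged over the defaults.

    ``overrides`` (same nested structure) are applied after the file.
    Raises :class:`ConfigError` listing *all* unknown keys, type
    mismatches and invariant violations found.
    """
    data: dict = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
            data = json.loads(text) if text.strip() else {}
        else:
            data = tomllib.loads(text)
    cfg = RunConfig()
    problems: list[str] = []
    _apply(cfg, data, "", problems)
    if overrides:
        _apply(cfg, overrides, "", problems)
    problems += cfg.validate()
    if problems:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))
    return cfg


def dump_config(cfg: RunConfig) -> dict:
    """Resolved config as a plain dict (for provenance echo)."""
    return dataclasses.asdict(cfg)
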