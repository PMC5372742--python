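"""Run configuration: one YAML file, flat sections, unknown keys rejected."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .census import CensusConfig
from .geometry import GeometryConfig


class ConfigError(ValueError):
    """Bad run configuration."""


@dataclass
class RunConfig:
    """Everything a command run needs besides its positional inputs.

    Sections: `geometry` (detection cutoff, ambiguity threshold),
    `census` (alignment scoring, length boundary, split override),
    `references` (path to a reference YAML for :func:`load_references`;
    empty means the synthetic stand-in references), plus `out_dir`,
    `seed` and `verbosity`. Flags given on the command line override the
    file.
    """

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    census: CensusConfig = field(default_factory=CensusConfig)
    references: str = ""
    out_dir: str = "."
    seed: int = 0
    verbosity: int = 1

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["census"]["hydrophobic_set"] = sorted(
            payload["census"]["hydrophobic_set"]
        )
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _build_section(cls, data: dict, section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in section {section!r}: {sorted(unknown)}")
    if "hydrophobic_set" in data:
        data = dict(data, hydrophobic_set=frozenset(data["hydrophobic_set"]))
    return cls(**data)


def load_config(path: str | None) -> RunConfig:
    """Load a RunConfig from YAML; None gives all defaults."""
    if path is None:
        return RunConfig()
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    known = {"geometry", "census", "references", "out_dir", "seed", "verbosity"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys {sorted(unknown)}")
    return RunConfig(
        geometry=_build_section(GeometryConfig, data.get("geometry", {}), "geometry"),
        census=_build_section(CensusConfig, data.get("census", {}), "census"),
        references=data.get("references", "") or "",
        out_dir=str(data.get("out_dir", ".")),
        seed=int(data.get("seed", 0)),
        verbosity=int(data.get("verbosity", 1)),
    )
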