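"""Configuration parsing, result serialization, and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
import time
from typing import Optional

import yaml

from .cell import CellConditions
from .fixtures import _condition_dict

__all__ = ["ConfigError", "load_config", "condition_from_config",
           "RunManifest", "write_manifest", "write_fit_parameters"]

try:
    from importlib.metadata import version as _pkg_version
    _VERSION = _pkg_version("anisoblock")
except Exception:  # pragma: no cover
    _VERSION = "unknown"


class ConfigError(ValueError):
    pass


_CONDITION_FIELDS = {"g_na", "g_cal", "g_kr", "g_ks", "g_k1", "ko", "ik1_rule", "cm"}
_KNOWN_SECTIONS = {"condition", "geometry", "simulation", "protocol", "reentry"}


def load_config(path, required: tuple = ()) -> dict:
    """Read a YAML config with sections mirroring the domain types.

    Raises :class:`ConfigError` naming the missing/unknown field.
    """
    p = pathlib.Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    cfg = yaml.safe_load(p.read_text()) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping of sections")
    for sec in cfg:
        if sec not in _KNOWN_SECTIONS:
            raise ConfigError(f"unknown config section {sec!r}")
    for sec in required:
        if sec not in cfg:
            raise ConfigError(f"missing required config section {sec!r}")
    cond = cfg.get("condition", {})
    for field in cond:
        if field not in _CONDITION_FIELDS:
            raise ConfigError(f"unknown condition field {field!r}")
    return cfg


def condition_from_config(cfg: dict) -> CellConditions:
    try:
        return CellConditions(**cfg.get("condition", {}))
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid condition: {e}") from e


@dataclasses.dataclass
class RunManifest:
    """Reproducibility metadata emitted once per CLI run."""

    command: str
    config: dict
    config_hash: str
    code_version: str
    outputs: list
    status: str
    wall_time_s: float

    def write(self, path) -> None:
        pathlib.Path(path).write_text(
            json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1) + "\n"
        )


def write_manifest(out_dir, command: str, config: dict, outputs: list,
                   status: str, wall_time_s: float) -> pathlib.Path:
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = RunManifest(
        command=command,
        config=config,
        config_hash=hashlib.sha256(blob.encode()).hexdigest(),
        code_version=_VERSION,
        outputs=[str(o) for o in outputs],
        status=status,
        wall_time_s=round(wall_time_s, 3),
    )
    path = pathlib.Path(out_dir) / "manifest.json"
    manifest.write(path)
    return path


def condition_config(cond: CellConditions) -> dict:
    return {"condition": _condition_dict(cond)}


def write_fit_parameters(path, fit) -> None:
    pathlib.Path(path).write_text(yaml.safe_dump({
        "ar1": fit.ar1, "a": fit.a, "b": fit.b, "c": fit.c, "d": fit.d,
    }, sort_keys=False))
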