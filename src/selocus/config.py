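"""Run configuration and report provenance.

A :class:`RunConfig` collects the knobs shared across pipeline stages
(seed, transmission parameters, fertility cut-offs, test level, optional
rule-table override).  The schema is strict: unknown keys are rejected so
typos cannot silently fall back to defaults.  Reports carry the config
hash, seed and package version so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Any, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig", "load_config", "build_report"]

try:
    _VERSION = version("selocus")
except PackageNotFoundError:  # pragma: no cover
    _VERSION = "unknown"


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    km: float = Field(default=1.0, ge=0.0, le=1.0)
    kf: float = Field(default=0.0, ge=0.0, le=1.0)
    fertility_low: float = Field(default=0.70, ge=0.0, le=1.0)
    fertility_high: float = Field(default=0.80, ge=0.0, le=1.0)
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    rules: Optional[list[dict]] = None

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config, or the defaults when ``path`` is None."""
    if path is None:
        return RunConfig()
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    return RunConfig(**data)


def build_report(payload: dict[str, Any], config: RunConfig) -> dict[str, Any]:
    """Wrap machine-readable results with reproducibility provenance."""
    return {
        "results": payload,
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": _VERSION,
        },
    }
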