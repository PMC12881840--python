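"""Run configuration (YAML) and report provenance helpers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .abstention import PADDINGS
from .classify import MODEL_KINDS


class RunConfig(BaseModel):
    """Knobs shared by the pipeline subcommands; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    confidence: float = Field(default=0.875, ge=0.0, le=1.0)
    model_kind: str = "svm_rbf"
    extractor: str = "toy-stats"
    patch_size_px: int = Field(default=4096, ge=224)
    patches_per_patient: int = Field(default=100, ge=1)
    train_fraction: float = Field(default=0.60, gt=0.0, lt=1.0)
    contains_zero_constraint: bool = True
    threshold_padding: str = "midpoint"

    @field_validator("model_kind")
    @classmethod
    def _check_model(cls, v: str) -> str:
        if v not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        return v

    @field_validator("threshold_padding")
    @classmethod
    def _check_padding(cls, v: str) -> str:
        if v not in PADDINGS:
            raise ValueError(f"threshold_padding must be one of {PADDINGS}")
        return v


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def file_fingerprint(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def make_report(config: RunConfig, inputs: dict[str, str | Path], payload: dict) -> dict:
    """Assemble a run report embedding config echo and input fingerprints."""
    cfg = config.model_dump()
    return {
        "package_version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {name: file_fingerprint(p) for name, p in inputs.items()},
        **payload,
    }
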