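"""Pipeline configuration: one nested, strictly validated structure.

Unknown keys are rejected, the resolved configuration round-trips
losslessly through YAML/JSON, and its SHA-256 hash stamps every output
so any artefact can be traced to the exact settings that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass
class PipelineConfig:
    """Defaults reproduce the standard three-group synthetic study."""

    seed: int = 0
    captures_per_eye: int = 3
    aggregation_mode: str = "weighted"  # or "best"
    adjust: str = "none"  # or "holm"
    # phantom overrides (None -> module defaults)
    n_frames: int | None = None
    speckle_contrast: float | None = None
    jitter_sd_px: float | None = None
    lateral_extent_um: float | None = None
    # segmentation
    score_override: int | None = None
    # io
    save_intermediates: bool = False

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.aggregation_mode not in ("weighted", "best"):
            raise ValueError("aggregation_mode must be 'weighted' or 'best'")
        if cfg.adjust not in ("none", "holm"):
            raise ValueError("adjust must be 'none' or 'holm'")
        return cfg


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON config file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return PipelineConfig.from_dict(data)


def config_hash(cfg: PipelineConfig) -> str:
    canon = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
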