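"""Run configuration: schema, validation, YAML loading and hashing.

One structured config file drives a whole run; CLI flags may override
individual fields.  Validation errors are reported with their field path
before any computation starts, and every output CSV embeds the config
hash and package version so results are traceable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, PositiveFloat, PositiveInt, ValidationError


class ConfigError(ValueError):
    """Configuration failed validation; message lists field paths."""


class RunConfig(BaseModel):
    """All tunable analysis parameters with their defaults."""

    pixel_size: PositiveFloat = 0.1083  # µm per pixel
    channel_roles: dict[str, int] = Field(
        default_factory=lambda: {
            "gamma_tubulin": 0,
            "alpha_tubulin": 1,
            "kinetochore": 2,
            "kif18a": 3,
        }
    )
    plate_channel: str = "kinetochore"  # marker fitted for alignment FWHM
    box_height: PositiveFloat = 5.0  # µm, boxed-profile height
    scan_width_px: PositiveInt = 10
    scan_length: PositiveFloat = 6.5  # µm, fixed-cell line-scan length
    reference_channel: str = "gamma_tubulin"
    target_channel: str = "kif18a"
    percent_grid_points: PositiveInt = 101
    ratio_floor_frac: float = Field(0.01, ge=0.0, lt=1.0)
    auc_variant: Literal["baseline_zero", "deviation"] = "baseline_zero"
    control_condition: str = "DMSO"
    seed: int = Field(0, ge=0)

    model_config = {"extra": "forbid"}

    def hash(self) -> str:
        """Short stable digest of the canonical config JSON."""
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def metadata(self) -> dict[str, str]:
        from . import __version__

        return {"config_hash": self.hash(), "spindlemetrics_version": __version__}


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML config (defaults if ``path`` is None), applying overrides.

    Raises :class:`ConfigError` naming each offending field path.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is not None:
            if not isinstance(raw, dict):
                raise ConfigError(f"{path}: config must be a mapping")
            data = raw
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return RunConfig(**data)
    except ValidationError as err:
        lines = [
            f"  {'.'.join(str(p) for p in e['loc']) or '<root>'}: {e['msg']}"
            for e in err.errors()
        ]
        raise ConfigError(
            "invalid configuration:\n" + "\n".join(lines)
        ) from None
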