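"""Run configuration: thresholds, input paths and conversion settings."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .data_io import ValidationError


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, YAML-round-trippable.

    When ``ct_path`` is unset the run simulates the default 18-gene
    preset instead of reading files (useful for smoke tests and demos).
    """

    ct_path: str | None = None
    sheet_path: str | None = None
    layout: str = "wide"
    dilutions_path: str | None = None
    efficiency: float = 1.0  # delta_ct fallback when no dilution series given
    aggregate_technical: bool = True
    max_spread: float = 0.5
    drop_incomplete: str | None = None  # None | "genes" | "samples"
    v_threshold: float = 0.15
    r_threshold: float = 0.9
    sd_flag_threshold: float = 1.0
    k_preselect: int = 10
    sd_convention: str = "sd"
    preselect_method: str = "sum"
    condition_set_column: str = "condition_set"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("v_threshold", "r_threshold", "sd_flag_threshold", "max_spread"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.k_preselect < 3:
            raise ValidationError("k_preselect must be >= 3")
        if self.drop_incomplete not in (None, "genes", "samples"):
            raise ValidationError(
                f"drop_incomplete must be None, 'genes' or 'samples', "
                f"got {self.drop_incomplete!r}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    def digest(self) -> str:
        """Stable hash of the configuration (for the run manifest)."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
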