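"""Run configuration: one JSON document driving an end-to-end run.

Unknown keys are rejected so a stale or typoed config fails loudly rather
than silently running with defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from .exceptions import ValidationError

_ENUMS = {
    "filter_order": ("pre", "post"),
    "lac_normalization": ("normalized", "raw", "cv2"),
    "ttest": ("welch", "student"),
    "extent_coding": ("quadrants", "binary"),
    "log_level": ("DEBUG", "INFO", "WARNING", "ERROR"),
}


@dataclass(frozen=True)
class RunConfig:
    filter_order: str = "pre"
    median_radius_px: int = 2
    box_sizes: tuple[int, ...] | str = "auto"
    n_origins: int = 4
    lac_normalization: str = "normalized"
    ttest: str = "welch"
    extent_coding: str = "quadrants"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for key, allowed in _ENUMS.items():
            if getattr(self, key) not in allowed:
                raise ValidationError(f"{key} must be one of {allowed}, got {getattr(self, key)!r}")
        if self.median_radius_px < 1:
            raise ValidationError("median_radius_px must be >= 1")
        if self.n_origins < 1:
            raise ValidationError("n_origins must be >= 1")
        if self.box_sizes != "auto":
            sizes = tuple(int(s) for s in self.box_sizes)  # type: ignore[union-attr]
            if len(sizes) < 3 or any(b <= a for a, b in zip(sizes, sizes[1:])):
                raise ValidationError("box_sizes must be >= 3 strictly increasing integers")
            object.__setattr__(self, "box_sizes", sizes)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if isinstance(d["box_sizes"], tuple):
            d["box_sizes"] = list(d["box_sizes"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"config is not valid JSON: {exc}") from exc
        if not isinstance(data, dict):
            raise ValidationError("config JSON must be an object")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "box_sizes" in data and isinstance(data["box_sizes"], list):
            data["box_sizes"] = tuple(data["box_sizes"])
        return cls(**data)

    @classmethod
    def from_file(cls, path: Path | str) -> "RunConfig":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))
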