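"""Run configuration: one YAML file per run, flags may override fields.

The config holds every tunable the pipeline exposes (detection, ring,
normalization mode, screen scoring, seed) so a run is fully described by
its config plus the input paths; the CLI writes the resolved values into
a run manifest for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detection import DetectionParams
from .quantify import RingParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    detection: DetectionParams = field(default_factory=DetectionParams)
    ring: RingParams = field(default_factory=RingParams)
    mode: str = "division"  # C/P normalization
    pseudocount: float = 0.5  # RPM
    n_perm: int = 10_000
    fdr_threshold: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("division", "subtraction"):
            raise ValueError(f"invalid config field mode={self.mode!r}")
        if self.n_perm < 100:
            raise ValueError(f"invalid config field n_perm={self.n_perm} (< 100)")
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError(f"invalid config field fdr_threshold={self.fdr_threshold}")
        if self.pseudocount < 0:
            raise ValueError(f"invalid config field pseudocount={self.pseudocount}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        kwargs = dict(raw)
        if "detection" in kwargs:
            det = dict(kwargs["detection"])
            for key in ("threshold", "area_px", "length_px"):
                if key in det and isinstance(det[key], list):
                    det[key] = tuple(det[key])
            kwargs["detection"] = DetectionParams(**det)
        if "ring" in kwargs:
            kwargs["ring"] = RingParams(**dict(kwargs["ring"]))
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))
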