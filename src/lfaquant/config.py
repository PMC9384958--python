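"""Run configuration: YAML (de)serialisation and content hashing.

A :class:`RunConfig` bundles every knob of the pipeline — phantom geometry,
detection windows, calibration settings, the concentration ladder and the root
seed — so a whole run is reproducible from one file. Each run emits the
resolved config together with a content hash; downstream steps refuse to mix
records produced under different hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import os
from dataclasses import dataclass, field

import yaml

from .calibrate import (
    DEFAULT_BAND_BOUNDS,
    DEFAULT_HIGH_RISK_THRESHOLD,
    DEFAULT_LOD_GRID,
    DEFAULT_WORKING_RANGE,
)
from .detect import DetectionConfig
from .errors import ConfigError
from .image import RoiRect
from .phantom import PhantomConfig

__all__ = ["RunConfig", "DEFAULT_LADDER"]

#: Default 10-point dilution ladder (ng/ml). The printed concentrations
#: 0/87/131/296/444/1000 come from the strip's visual grading groups; the
#: remaining four are evenly interleaved to cover the working range.
DEFAULT_LADDER = (0.0, 50.0, 87.0, 131.0, 200.0, 296.0, 444.0, 600.0, 800.0, 1000.0)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce an end-to-end simulate/analyze/calibrate run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    concentrations: tuple[float, ...] = DEFAULT_LADDER
    replicates: int = 5
    ratio_kind: str = "ratio_tb"
    working_range: tuple[float, float] = DEFAULT_WORKING_RANGE
    high_threshold: float = DEFAULT_HIGH_RISK_THRESHOLD
    band_bounds: tuple[float, float] = DEFAULT_BAND_BOUNDS
    lod_sigma_r: float = 0.07
    lod_k: float = 2.0
    lod_grid: tuple[float, ...] = DEFAULT_LOD_GRID
    seed: int = 0
    out_dir: str = "lfaquant_out"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("concentrations", "working_range", "band_bounds", "lod_grid"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        try:
            if "phantom" in d:
                ph = dict(d["phantom"])
                if "roi" in ph and not isinstance(ph["roi"], RoiRect):
                    ph["roi"] = RoiRect(**ph["roi"])
                d["phantom"] = PhantomConfig(**ph)
            if "detection" in d:
                d["detection"] = DetectionConfig(**d["detection"])
            for key in ("concentrations", "working_range", "band_bounds", "lod_grid"):
                if key in d:
                    d[key] = tuple(float(x) for x in d[key])
            return cls(**d)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid run configuration: {exc}") from exc

    def to_yaml(self, path: str | os.PathLike | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: expected a YAML mapping")
        return cls.from_dict(d)

    def content_hash(self) -> str:
        """Short stable hash of the resolved configuration."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
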