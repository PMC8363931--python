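"""Run configuration: one home for every tunable, YAML round-trippable."""

from __future__ import annotations

import dataclasses
import hashlib
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .zones import ZoneConfig

__all__ = ["RunConfig", "stage_seed", "config_hash"]

VERSION = "0.1.0"


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serialized losslessly to YAML."""

    seed: int = 0
    # simulation
    n_patients: int = 24
    cores_per_patient: int = 2
    frame_px: int = 128
    core_diameter_um: float = 1000.0
    beta: float = 0.0  # log-hazard per scaled unit of the effect variable
    effect_marker: str = "PDGFRB"
    effect_compartment: str = "meso"
    marker_distribution: tuple = ("uniform", 0.05, 0.45)
    baseline_hazard: float = 0.04
    censor_rate: float = 3.0 / 74.0
    noise_sd: float = 0.05
    round2_max_shift_px: int = 3
    # registration / QC
    reference_channel: str = "DAPI"
    max_shift_um: float = 60.0
    min_tissue_fraction: float = 0.1
    # segmentation
    classifier_trees: int = 30
    train_pixels_per_class: int = 1500
    tumor_threshold: float | None = None  # None -> Otsu per core
    # zones
    zone_width_um: float = 12.0
    n_zones: int = 4
    # quantification
    positivity_threshold: float | None = None
    confidence_threshold: float = 0.85
    # survival
    bonferroni_m: int | None = None
    adjusters: tuple = ("age", "sex", "side", "stage", "histology")
    compute_ph: bool = True
    # bookkeeping
    write_images: bool = False
    version: str = VERSION

    @property
    def pixel_size_um(self) -> float:
        return self.core_diameter_um / self.frame_px

    @property
    def zone_config(self) -> ZoneConfig:
        return ZoneConfig(self.zone_width_um, self.n_zones)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(_plain(dataclasses.asdict(self)),
                              sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_yaml(source: str | Path) -> "RunConfig":
        text = Path(source).read_text() if isinstance(source, Path) or \
            ("\n" not in str(source) and Path(str(source)).exists()) \
            else str(source)
        data = yaml.safe_load(text) or {}
        fields = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("marker_distribution", "adjusters"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return RunConfig(**data)


def _plain(obj):
    """YAML-safe copy (tuples to lists, numpy scalars to python)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item") and not isinstance(obj, (str, bytes)):
        return obj.item()
    return obj


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Fan one global seed out to a per-stage seed (stage-name hashing), so
    each stage is independently reproducible."""
    return (seed ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF
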