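"""Pipeline configuration: per-channel reconstruction parameters + profiles.

Two shipped profiles:

* ``fullscale`` — the reference parameter set for full-scale human
  spleen ROIs (2000 px crop, 83 sections, octree depths 9/7/8, iso-values
  100/160, component-removal fractions 2/10/5 %, decimation to 10/50 %);
* ``desk`` — the same recipe scaled to the 320 px × 40-section phantom used
  for development and testing; octree depths are one level lower so the
  absolute repair cell size stays at or below the full-scale one.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .phantom import PhantomSpec
from .stain import StainModel

__all__ = ["ChannelConfig", "PipelineConfig", "fullscale_profile", "desk_profile"]


@dataclass
class ChannelConfig:
    iso: float
    interp_factor: int
    interp_mode: str  # 'flow' | 'nearest' | 'none'
    octree_depth: int
    component_fraction: float | None  # None = keep all components
    decimate_fraction: float | None  # None = no decimation
    smooth: bool = True


@dataclass
class PipelineConfig:
    pixel_size_um: float = 0.5
    thickness_um: float = 7.0
    crop_px: int = 2000
    registration_sigma: float = 6.0
    registration_seed: int = 0
    reinhard_reference_index: int = 0
    background_percentile: float = 99.0
    paint_threshold_um: float = 8.75
    prune_max_distance_um: float = 25.0
    prune_min_diameter_um: float = 10.0
    taubin_iterations: int = 10
    recovery_tolerance_um: float = 5.0
    stain_matrix: list = field(
        default_factory=lambda: StainModel().od_matrix.tolist()
    )
    channels: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=dict)

    def channel(self, name: str) -> ChannelConfig:
        return ChannelConfig(**self.channels[name])

    def stain_model(self) -> StainModel:
        return StainModel(od_matrix=np.asarray(self.stain_matrix))

    def phantom_spec(self) -> PhantomSpec:
        d = dict(self.phantom)
        for key in ("domain_size_um", "branches_per_arteriole",
                    "sheath_bifurcation_depth", "side_branches_per_sheath",
                    "jitter_translation_px", "jitter_rotation_deg",
                    "stem_segments", "stem_segment_um", "branch_segment_um",
                    "sheath_segment_um", "network_segments",
                    "network_segment_um", "lost_section_indices"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return PhantomSpec(**d)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        if isinstance(source, Path) or (isinstance(source, str)
                                        and "\n" not in source
                                        and Path(source).exists()):
            text = Path(source).read_text()
        else:
            text = source
        doc = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for name, block in doc.get("channels", {}).items():
            bad = set(block) - {f.name for f in dataclasses.fields(ChannelConfig)}
            if bad:
                raise ValueError(f"unknown channel keys for {name}: {sorted(bad)}")
        return cls(**doc)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def fullscale_profile() -> PipelineConfig:
    """Reference parameters for the full-scale spleen reconstruction."""
    return PipelineConfig(
        crop_px=2000,
        channels={
            "CD34": dict(iso=100, interp_factor=7, interp_mode="flow",
                         octree_depth=9, component_fraction=0.02,
                         decimate_fraction=0.10, smooth=True),
            "SMA": dict(iso=160, interp_factor=7, interp_mode="flow",
                        octree_depth=7, component_fraction=0.10,
                        decimate_fraction=None, smooth=True),
            "CD271": dict(iso=160, interp_factor=7, interp_mode="flow",
                          octree_depth=8, component_fraction=0.05,
                          decimate_fraction=0.50, smooth=True),
            "CD20": dict(iso=100, interp_factor=1, interp_mode="nearest",
                         octree_depth=8, component_fraction=None,
                         decimate_fraction=0.50, smooth=False),
        },
        phantom=dict(
            domain_size_um=[1000.0, 1000.0, 581.0],
        ),
    )


def desk_profile(seed: int = 0) -> PipelineConfig:
    """Desk-scale profile: 320 px × 40 sections, one octree level lower."""
    cfg = fullscale_profile()
    cfg.crop_px = 320
    for name, depth in (("CD34", 8), ("SMA", 7), ("CD271", 7), ("CD20", 7)):
        cfg.channels[name]["octree_depth"] = depth
    cfg.phantom = dict(seed=seed)
    return cfg
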