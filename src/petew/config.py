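"""Pipeline configuration: scanner, windows, binning, reconstruction.

One YAML document configures a full study; every field has the default
used throughout the validation fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .calibration import EnergyWindowConfig
from .geometry import LORBinner, ScannerGeometry, VirtualPixelGrid

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """Study configuration with desk-scale defaults."""

    geometry: ScannerGeometry = field(default_factory=ScannerGeometry)
    window_mode: str = "TEW"            # "DEW" | "TEW"
    pixel_pitch: float = 2.0            # mm, estimation LOR binning
    detector_model: str = "full_absorption"  # or "cascade"
    coefficient_mode: str = "global"    # "global" | "per_bin"
    count_floor: int = 50               # per-bin calibration floor
    # reconstruction
    recon_pixel_pitch: float = 5.0      # mm, LOR discretisation of the system model
    voxel_size: tuple = (4.0, 4.0, 10.0)  # mm
    volume_extent: tuple = (220.0, 220.0, 50.0)  # mm
    n_iter: int = 4
    n_subsets: int = 3

    def window_config(self) -> EnergyWindowConfig:
        return EnergyWindowConfig(mode=self.window_mode,
                                  acceptance=self.geometry.acceptance_window)

    def binner(self) -> LORBinner:
        grid = VirtualPixelGrid(self.pixel_pitch, self.geometry.block_width,
                                self.geometry.block_height)
        return LORBinner(self.geometry, grid)

    def recon_binner(self) -> LORBinner:
        grid = VirtualPixelGrid(self.recon_pixel_pitch,
                                self.geometry.block_width,
                                self.geometry.block_height)
        return LORBinner(self.geometry, grid)

    def volume_shape(self) -> tuple[int, int, int]:
        return tuple(max(1, int(round(e / v)))
                     for e, v in zip(self.volume_extent, self.voxel_size))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = self.geometry.to_dict()
        d["voxel_size"] = list(self.voxel_size)
        d["volume_extent"] = list(self.volume_extent)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "geometry" in d:
            d["geometry"] = ScannerGeometry.from_dict(d["geometry"])
        for key in ("voxel_size", "volume_extent"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def load_config(path) -> PipelineConfig:
    with open(path) as f:
        return PipelineConfig.from_dict(yaml.safe_load(f) or {})


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg.to_dict(), f, sort_keys=True)
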