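"""Voxel volumes.

A :class:`VoxelVolume` is a 3-D scalar grid indexed (slice, row, column)
with voxel spacing in mm.  World coordinates put the origin at the
isocenter: x runs along columns (+x right), y along rows (+y up, so row
index increases downward), z along slices.  Values are either CT
numbers (``is_hu=True``, water = 0, air = -1000, float, extended scale)
or linear attenuation coefficients in 1/cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["VoxelVolume"]


@dataclass
class VoxelVolume:
    data: np.ndarray  # (nz, ny, nx) float
    spacing_mm: tuple[float, float, float]  # (dz, dy, dx)
    is_hu: bool = True
    origin_mm: tuple[float, float, float] | None = None  # world (z,y,x) of voxel (0,0,0) center
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D (slice, row, column)")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.origin_mm is None:
            nz, ny, nx = self.data.shape
            dz, dy, dx = self.spacing_mm
            # centered on the isocenter; y axis up means origin row is at +y
            self.origin_mm = (
                -0.5 * (nz - 1) * dz,
                +0.5 * (ny - 1) * dy,
                -0.5 * (nx - 1) * dx,
            )
        else:
            self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_coords(self):
        """World (z, y, x) coordinate vectors of the voxel centers, in mm."""
        nz, ny, nx = self.data.shape
        dz, dy, dx = self.spacing_mm
        oz, oy, ox = self.origin_mm
        z = oz + np.arange(nz) * dz
        y = oy - np.arange(ny) * dy  # +y up, row index downward
        x = ox + np.arange(nx) * dx
        return z, y, x

    def copy(self) -> "VoxelVolume":
        return replace(self, data=self.data.copy(), meta=dict(self.meta))

    def same_grid(self, other: "VoxelVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def like(self, data: np.ndarray, **overrides) -> "VoxelVolume":
        """A new volume on this grid carrying ``data``."""
        if data.shape != self.shape:
            raise ValueError("data shape does not match grid")
        kwargs = dict(
            spacing_mm=self.spacing_mm,
            is_hu=self.is_hu,
            origin_mm=self.origin_mm,
            meta=dict(self.meta),
        )
        kwargs.update(overrides)
        return VoxelVolume(data=np.asarray(data, dtype=float), **kwargs)
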