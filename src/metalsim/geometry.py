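"""Acquisition geometry.

Desk-scale 2-D multi-slice geometry: a parallel- or fan-beam system
applied slice by slice, with detector row index j addressing independent
axial slices.  World coordinates are millimetres with the origin at the
isocenter; view angle 0 sends rays along +y, and increasing angles
rotate counter-clockwise.  The field of view is the circle inscribed in
the detector shadow; objects must fit inside it (see the projector's
truncation check).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["AcquisitionGeometry"]


@dataclass(frozen=True)
class AcquisitionGeometry:
    beam: str  # "parallel" | "fan"
    n_views: int
    n_cols: int
    n_rows: int
    det_pitch_mm: float
    fov_mm: float
    angular_range: float = field(default=None)  # radians; default pi or 2*pi
    sid_mm: float | None = None  # source-to-isocenter (fan only)
    sdd_mm: float | None = None  # source-to-detector (fan only)

    def __post_init__(self):
        if self.beam not in ("parallel", "fan"):
            raise ValueError(f"beam must be 'parallel' or 'fan', got {self.beam!r}")
        if self.n_views < 1 or self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("views, columns and rows must be positive")
        if self.det_pitch_mm <= 0 or self.fov_mm <= 0:
            raise ValueError("detector pitch and FOV must be positive")
        if self.angular_range is None:
            object.__setattr__(
                self, "angular_range", math.pi if self.beam == "parallel" else 2.0 * math.pi
            )
        if self.beam == "fan":
            if not self.sid_mm or not self.sdd_mm:
                raise ValueError("fan beam requires sid_mm and sdd_mm")
            if self.sdd_mm <= self.sid_mm:
                raise ValueError("source-detector distance must exceed source-isocenter")
            if self.fov_mm / 2.0 >= self.sid_mm:
                raise ValueError("FOV must be smaller than the source orbit")
            half_fan = math.atan(0.5 * self.n_cols * self.det_pitch_mm / self.sdd_mm)
            if math.asin(0.5 * self.fov_mm / self.sid_mm) > half_fan + 1e-12:
                raise ValueError("FOV circle is not inscribed in the detector fan")
        else:
            if self.n_cols * self.det_pitch_mm < self.fov_mm - 1e-9:
                raise ValueError("detector extent does not cover the FOV")

    # -- derived ------------------------------------------------------------

    @property
    def view_angles(self) -> np.ndarray:
        """Uniform view angles in [0, angular_range)."""
        return np.arange(self.n_views) * (self.angular_range / self.n_views)

    @property
    def detector_s_mm(self) -> np.ndarray:
        """Detector channel coordinates (mm), centered on the central ray."""
        return (np.arange(self.n_cols) - 0.5 * (self.n_cols - 1)) * self.det_pitch_mm

    @property
    def sinogram_shape(self) -> tuple[int, int, int]:
        return (self.n_views, self.n_cols, self.n_rows)

    # -- constructors / IO --------------------------------------------------

    @classmethod
    def parallel(cls, fov_mm=250.0, n_views=360, det_pitch_mm=1.0, n_rows=1, n_cols=None):
        if n_cols is None:
            n_cols = int(math.ceil(fov_mm / det_pitch_mm)) + 8
        return cls(
            beam="parallel",
            n_views=n_views,
            n_cols=n_cols,
            n_rows=n_rows,
            det_pitch_mm=det_pitch_mm,
            fov_mm=fov_mm,
        )

    @classmethod
    def fan(cls, fov_mm=250.0, n_views=720, det_pitch_mm=1.0, n_rows=1,
            sid_mm=595.0, sdd_mm=1085.6, n_cols=None):
        if n_cols is None:
            mag = sdd_mm / sid_mm
            n_cols = int(math.ceil(mag * fov_mm / det_pitch_mm)) + 16
        return cls(
            beam="fan",
            n_views=n_views,
            n_cols=n_cols,
            n_rows=n_rows,
            det_pitch_mm=det_pitch_mm,
            fov_mm=fov_mm,
            sid_mm=sid_mm,
            sdd_mm=sdd_mm,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AcquisitionGeometry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
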