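"""Quantitative artifact and image-quality metrics.

ROI noise follows the phantom-measurement protocol: the standard
deviation is computed per slice inside the ROI and then averaged over
slices (with the across-slice SD of those values as the uncertainty),
not pooled over the whole stack.

Artifact volume is quantified by histogramming voxels below -75 HU
(dark streaks) and within [75, 500] HU (bright blooming); the 75-HU
band corresponds to about three standard deviations of a water-only
histogram, and the 500-HU cap excludes the metallic device itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import VoxelVolume

__all__ = [
    "RoiSpec",
    "RoiNoise",
    "roi_noise",
    "ArtifactHistogram",
    "artifact_histogram",
    "sinogram_difference",
    "dice_overlap",
]


@dataclass(frozen=True)
class RoiSpec:
    """Circular or rectangular in-plane ROI over a slice range."""

    shape: str  # "circle" | "rectangle"
    center: tuple[int, int]  # (row, col)
    radius: int | None = None  # circle, voxels
    extents: tuple[int, int] | None = None  # rectangle half-sizes (rows, cols)
    slices: slice | None = None  # default: all slices

    def mask(self, ny: int, nx: int) -> np.ndarray:
        cy, cx = self.center
        if self.shape == "circle":
            if self.radius is None:
                raise ValueError("circular ROI needs a radius")
            yy, xx = np.ogrid[:ny, :nx]
            m = (yy - cy) ** 2 + (xx - cx) ** 2 <= self.radius**2
        elif self.shape == "rectangle":
            if self.extents is None:
                raise ValueError("rectangular ROI needs extents")
            ey, ex = self.extents
            m = np.zeros((ny, nx), bool)
            m[max(cy - ey, 0):cy + ey + 1, max(cx - ex, 0):cx + ex + 1] = True
        else:
            raise ValueError(f"unknown ROI shape {self.shape!r}")
        return m

    def validate_inside(self, ny: int, nx: int) -> None:
        cy, cx = self.center
        if self.shape == "circle":
            r = self.radius or 0
            ok = (cy - r >= 0 and cx - r >= 0 and cy + r < ny and cx + r < nx)
        else:
            ey, ex = self.extents or (0, 0)
            ok = (cy - ey >= 0 and cx - ex >= 0 and cy + ey < ny and cx + ex < nx)
        if not ok:
            raise ValueError("ROI extends outside the volume")


@dataclass(frozen=True)
class RoiNoise:
    mean_hu: float
    sd_hu: float  # mean of the per-slice SDs
    per_slice_sd: np.ndarray
    sd_across_slices: float  # SD of the per-slice SDs
    degenerate: bool = False  # single-voxel ROI


def roi_noise(volume: VoxelVolume, roi: RoiSpec) -> RoiNoise:
    """Mean and noise (SD) of an ROI, slice-averaged."""
    nz, ny, nx = volume.shape
    roi.validate_inside(ny, nx)
    mask = roi.mask(ny, nx)
    sl = roi.slices if roi.slices is not None else slice(None)
    stack = volume.data[sl][:, mask]
    if stack.size == 0:
        raise ValueError("ROI selects no voxels")
    degenerate = stack.shape[1] < 2
    per_slice_sd = stack.std(axis=1, ddof=1) if not degenerate else np.zeros(stack.shape[0])
    return RoiNoise(
        mean_hu=float(stack.mean()),
        sd_hu=float(per_slice_sd.mean()),
        per_slice_sd=per_slice_sd,
        sd_across_slices=float(per_slice_sd.std(ddof=1)) if len(per_slice_sd) > 1 else 0.0,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class ArtifactHistogram:
    low_count: int  # voxels below the dark threshold
    high_count: int  # voxels in the bright band
    low_hist: tuple  # (counts, bin_edges)
    high_hist: tuple
    total_considered: int
    thresholds: tuple[float, float, float]

    @property
    def artifact_count(self) -> int:
        return self.low_count + self.high_count


def artifact_histogram(volume: VoxelVolume, exclusion_mask=None,
                       thresholds=(-75.0, 75.0, 500.0),
                       bin_width: float = 5.0) -> ArtifactHistogram:
    """Histogram of artifact voxels: HU < t_low or t_high <= HU <= t_cap.

    ``exclusion_mask`` (optional boolean array) removes voxels, e.g. a
    dilated probe mask when streaks exceed the metal cap.
    """
    t_low, t_high, t_cap = thresholds
    if not (t_low < t_high < t_cap):
        raise ValueError("thresholds must be ordered (low < high < cap)")
    data = volume.data
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, bool)
        if exclusion_mask.shape != data.shape:
            raise ValueError("exclusion mask shape mismatch")
        data = data[~exclusion_mask]
    low = data[data < t_low]
    high = data[(data >= t_high) & (data <= t_cap)]
    lo_edge = np.floor(min(low.min(), t_low) / bin_width) * bin_width if low.size else t_low
    low_hist = np.histogram(low, bins=np.arange(lo_edge, t_low + bin_width, bin_width))
    high_hist = np.histogram(high, bins=np.arange(t_high, t_cap + bin_width, bin_width))
    return ArtifactHistogram(
        low_count=int(low.size),
        high_count=int(high.size),
        low_hist=low_hist,
        high_hist=high_hist,
        total_considered=int(data.size),
        thresholds=(float(t_low), float(t_high), float(t_cap)),
    )


def sinogram_difference(sino_a, sino_b, roi: RoiSpec | None = None,
                        detector_row: int | None = None):
    """Elementwise difference map a - b with optional ROI statistics.

    Inputs are sinogram objects or raw arrays of identical shape.
    ``detector_row`` selects a single row j, returning a 2-D
    (view, column) map as when inspecting the central detector row.
    Returns ``(difference, stats)``; stats is None without an ROI.
    """
    a = getattr(sino_a, "values", sino_a)
    b = getattr(sino_b, "values", sino_b)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"sinogram shapes differ: {a.shape} vs {b.shape}")
    diff = a - b
    if detector_row is not None:
        diff = diff[:, :, detector_row]
    stats = None
    if roi is not None:
        ny, nx = diff.shape[-2:] if diff.ndim == 2 else (diff.shape[0], diff.shape[1])
        plane = diff if diff.ndim == 2 else diff[:, :, 0]
        roi.validate_inside(*plane.shape)
        vals = plane[roi.mask(*plane.shape)]
        stats = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
    return diff, stats


def dice_overlap(volume_a, volume_b, threshold_hu: float) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) of thresholded metal masks.

    Two empty masks overlap perfectly by convention (returns 1.0).
    """
    a = volume_a.data if isinstance(volume_a, VoxelVolume) else np.asarray(volume_a)
    b = volume_b.data if isinstance(volume_b, VoxelVolume) else np.asarray(volume_b)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    if isinstance(volume_a, VoxelVolume) and isinstance(volume_b, VoxelVolume):
        if not volume_a.same_grid(volume_b):
            raise ValueError("volumes are not on the same grid")
    ma = a > threshold_hu
    mb = b > threshold_hu
    denom = ma.sum() + mb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(ma, mb).sum() / denom)
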