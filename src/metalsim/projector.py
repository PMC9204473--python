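"""CT forward projection and filtered back projection.

Stands in for the scanner and the vendor reconstructor: linear
attenuation volumes are forward projected slice by slice into
dimensionless line integrals P = integral of mu dl (mu in 1/cm, path in
cm), and sinograms are reconstructed by filtered back projection.

Conventions
-----------
* Volumes are indexed (slice, row, column); world origin at isocenter,
  +x along columns, +y up (row index increases downward).
* View angle 0 sends rays along +y; angles increase counter-clockwise.
* Parallel rays at angle theta run along (-sin t, cos t) and are
  indexed by the signed detector coordinate s along (cos t, sin t).
* Ray integration uses Joseph-style bilinear interpolation sampled at
  half-voxel steps.
* Fan-beam sinograms are rebinned to parallel geometry before
  filtering; reconstruction itself always happens in parallel geometry
  (scikit-image's ``iradon``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import ConvexHull, Delaunay, QhullError
from skimage.transform import iradon

from .geometry import AcquisitionGeometry
from .volume import VoxelVolume

__all__ = [
    "Sinogram",
    "hu_to_lac",
    "lac_to_hu",
    "forward_project",
    "fbp_reconstruct",
    "apply_window",
    "TruncationError",
]

KERNELS = {
    "smooth": "hann",  # Br40-analog apodization; no vendor-kernel equivalence claimed
    "sharp": "ramp",   # Br70 analog
    "ramp": "ramp",
    "hann": "hann",
    "hamming": "hamming",
    "cosine": "cosine",
    "shepp-logan": "shepp-logan",
}


class TruncationError(ValueError):
    """Raised when the object support projects beyond the detector."""


@dataclass
class Sinogram:
    """Projection array P(view, column, row) of dimensionless line integrals."""

    values: np.ndarray  # (n_views, n_cols, n_rows)
    geometry: AcquisitionGeometry
    kvp: float | None = None
    n0: float | np.ndarray | None = None  # incident quanta per element per view
    mu_water_per_cm: float | None = None  # HU reference used by the chain
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.sinogram_shape:
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"{self.geometry.sinogram_shape}"
            )


# ---------------------------------------------------------------------------
# HU <-> LAC

def hu_to_lac(volume: VoxelVolume, mu_water_per_cm: float) -> VoxelVolume:
    """Convert CT numbers to linear attenuation, mu = mu_w (1 + HU/1000).

    Values below -1000 HU clamp to zero attenuation.
    """
    if mu_water_per_cm <= 0:
        raise ValueError("reference water attenuation must be positive")
    lac = mu_water_per_cm * (1.0 + volume.data / 1000.0)
    np.clip(lac, 0.0, None, out=lac)
    return volume.like(lac, is_hu=False, meta={**volume.meta, "mu_water_per_cm": mu_water_per_cm})


def lac_to_hu(volume: VoxelVolume, mu_water_per_cm: float) -> VoxelVolume:
    """Inverse of :func:`hu_to_lac` (exact for nonnegative LAC)."""
    if mu_water_per_cm <= 0:
        raise ValueError("reference water attenuation must be positive")
    hu = 1000.0 * (volume.data - mu_water_per_cm) / mu_water_per_cm
    return volume.like(hu, is_hu=True, meta={**volume.meta, "mu_water_per_cm": mu_water_per_cm})


# ---------------------------------------------------------------------------
# forward projection

def _support_hull_points(volume: VoxelVolume):
    """World (x, y) convex-hull vertices of the in-plane support, or None."""
    mask2d = np.any(volume.data > 1e-9, axis=0)
    if not mask2d.any():
        return None
    rr, cc = np.nonzero(mask2d)
    _, y, x = volume.world_coords()
    pts = np.column_stack([x[cc], y[rr]])
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (collinear) support; use raw points
    return pts


def _check_truncation(volume, geometry, hull):
    if hull is None:
        return
    margin = 0.5 * float(np.hypot(volume.spacing_mm[1], volume.spacing_mm[2]))
    half_extent = 0.5 * geometry.n_cols * geometry.det_pitch_mm
    angles = geometry.view_angles
    if geometry.beam == "parallel":
        s = hull[:, 0][None, :] * np.cos(angles)[:, None] + hull[:, 1][None, :] * np.sin(
            angles
        )[:, None]
        smax = np.abs(s).max(axis=1) + margin
        bad = np.nonzero(smax > half_extent)[0]
    else:
        bad = []
        for iv, beta in enumerate(angles):
            src = np.array([geometry.sid_mm * np.sin(beta), -geometry.sid_mm * np.cos(beta)])
            d_hat = np.array([-np.sin(beta), np.cos(beta)])
            u_hat = np.array([np.cos(beta), np.sin(beta)])
            rel = hull - src
            u = geometry.sdd_mm * (rel @ u_hat) / (rel @ d_hat)
            if np.abs(u).max() + margin > half_extent:
                bad.append(iv)
        bad = np.asarray(bad)
    if len(bad):
        shown = ", ".join(str(int(b)) for b in bad[:8])
        more = "" if len(bad) <= 8 else f" (+{len(bad) - 8} more)"
        raise TruncationError(
            f"object support projects beyond the detector in {len(bad)} view(s): "
            f"{shown}{more}; enlarge the detector/FOV or pass allow_truncation=True"
        )


def _bilinear_rays(data, rows, cols):
    """Sample a slice stack (nz, ny, nx) at fractional (rows, cols) -> (nz, M)."""
    nz, ny, nx = data.shape
    r0 = np.floor(rows).astype(np.intp)
    c0 = np.floor(cols).astype(np.intp)
    fr = rows - r0
    fc = cols - c0
    out = np.zeros((nz, rows.size), dtype=float)
    flat = data.reshape(nz, -1)
    for dr, wr in ((0, 1.0 - fr), (1, fr)):
        ri = r0 + dr
        rv = (ri >= 0) & (ri < ny)
        for dc, wc in ((0, 1.0 - fc), (1, fc)):
            ci = c0 + dc
            ok = rv & (ci >= 0) & (ci < nx)
            if not ok.any():
                continue
            idx = np.nonzero(ok)[0]
            w = wr[idx] * wc[idx]
            out[:, idx] += flat[:, ri[idx] * nx + ci[idx]] * w
    return out


def forward_project(
    volume: VoxelVolume,
    geometry: AcquisitionGeometry,
    allow_truncation: bool = False,
) -> Sinogram:
    """Line integrals of a linear-attenuation volume.

    The volume must hold LAC values in 1/cm (``is_hu=False``); the
    number of slices must equal the geometry's detector row count.
    Raises :class:`TruncationError` when the support projects beyond
    the detector, naming the offending views.
    """
    if volume.is_hu:
        raise ValueError("forward projection needs a LAC volume; convert with hu_to_lac")
    nz, ny, nx = volume.shape
    if nz != geometry.n_rows:
        raise ValueError(
            f"volume has {nz} slice(s) but geometry expects {geometry.n_rows} detector row(s)"
        )
    hull = _support_hull_points(volume)
    if not allow_truncation:
        _check_truncation(volume, geometry, hull)

    dz, dy, dx = volume.spacing_mm
    oz, oy, ox = volume.origin_mm
    step_mm = 0.5 * min(dy, dx)
    data = volume.data

    # integration reach: cover the support (or FOV) with a small margin
    if hull is None:
        return Sinogram(
            np.zeros(geometry.sinogram_shape), geometry,
            mu_water_per_cm=volume.meta.get("mu_water_per_cm"),
        )
    r_sup = float(np.hypot(hull[:, 0], hull[:, 1]).max()) + 2.0 * max(dy, dx)

    s = geometry.detector_s_mm
    p = np.empty(geometry.sinogram_shape, dtype=float)
    t = np.arange(-r_sup, r_sup + step_mm, step_mm)

    for iv, ang in enumerate(geometry.view_angles):
        if geometry.beam == "parallel":
            ux, uy = np.cos(ang), np.sin(ang)
            dxr, dyr = -np.sin(ang), np.cos(ang)
            # (n_cols, n_steps) sample points
            px = s[:, None] * ux + t[None, :] * dxr
            py = s[:, None] * uy + t[None, :] * dyr
            seg = np.full(s.shape, step_mm)
        else:
            src = np.array([geometry.sid_mm * np.sin(ang), -geometry.sid_mm * np.cos(ang)])
            d_hat = np.array([-np.sin(ang), np.cos(ang)])
            u_hat = np.array([np.cos(ang), np.sin(ang)])
            det = src + geometry.sdd_mm * d_hat[None, :] + s[:, None] * u_hat[None, :]
            rays = det - src[None, :]
            rays /= np.linalg.norm(rays, axis=1, keepdims=True)
            tf = np.arange(geometry.sid_mm - r_sup, geometry.sid_mm + r_sup + step_mm, step_mm)
            px = src[0] + rays[:, 0:1] * tf[None, :]
            py = src[1] + rays[:, 1:2] * tf[None, :]
            seg = np.full(s.shape, step_mm)
        cols = (px - ox) / dx
        rows = (oy - py) / dy
        vals = _bilinear_rays(data, rows.ravel(), cols.ravel())
        sums = vals.reshape(nz, len(s), -1).sum(axis=2)
        p[iv] = (sums * seg[None, :] / 10.0).T  # mm -> cm, (n_cols, nz)

    return Sinogram(
        p, geometry, mu_water_per_cm=volume.meta.get("mu_water_per_cm"),
        meta={"source": "forward_project"},
    )


# ---------------------------------------------------------------------------
# fan -> parallel rebinning

def _rebin_fan_to_parallel(sino: Sinogram, n_par_views: int, s_grid: np.ndarray):
    """Resample a full-scan fan sinogram onto a parallel (theta, s) grid."""
    g = sino.geometry
    beta = g.view_angles
    gamma = np.arctan(g.detector_s_mm / g.sdd_mm)
    th = (beta[:, None] + gamma[None, :]) % (2.0 * np.pi)
    sv = g.sid_mm * np.sin(gamma)[None, :] * np.ones_like(beta)[:, None]
    flip = th >= np.pi
    th = np.where(flip, th - np.pi, th)
    sv = np.where(flip, -sv, sv)

    pts = np.column_stack([th.ravel(), sv.ravel()])
    vals = sino.values.reshape(len(beta) * len(gamma), g.n_rows)
    # periodic continuation across theta = 0 / pi so interpolation has support
    band = 3.0 * np.pi / n_par_views + np.abs(gamma).max()
    lo = pts[:, 0] < band
    hi = pts[:, 0] > np.pi - band
    pts_ext = np.vstack(
        [pts, pts[lo] + [np.pi, 0], pts[hi] - [np.pi, 0]]
    )
    pts_ext[len(pts):, 1] *= -1
    vals_ext = np.vstack([vals, vals[lo], vals[hi]])

    tri = Delaunay(pts_ext)
    theta_par = np.arange(n_par_views) * np.pi / n_par_views
    TH, S = np.meshgrid(theta_par, s_grid, indexing="ij")
    out = np.empty((n_par_views, len(s_grid), g.n_rows))
    for j in range(g.n_rows):
        interp = LinearNDInterpolator(tri, vals_ext[:, j], fill_value=0.0)
        out[:, :, j] = interp(TH, S)
    par_geo = AcquisitionGeometry(
        beam="parallel",
        n_views=n_par_views,
        n_cols=len(s_grid),
        n_rows=g.n_rows,
        det_pitch_mm=float(s_grid[1] - s_grid[0]) if len(s_grid) > 1 else g.det_pitch_mm,
        fov_mm=g.fov_mm,
    )
    return Sinogram(out, par_geo, kvp=sino.kvp, mu_water_per_cm=sino.mu_water_per_cm)


# ---------------------------------------------------------------------------
# filtered back projection

def fbp_reconstruct(
    sinogram: Sinogram,
    kernel: str = "smooth",
    output_size: int | None = None,
    voxel_mm: float | None = None,
    slice_thickness_mm: float | None = None,
    mu_water_per_cm: float | None = None,
    output: str = "hu",
) -> VoxelVolume:
    """Filtered back projection onto a square grid.

    ``kernel`` selects the apodization: ``"smooth"`` (Hann-weighted
    ramp, medium-sharp analog) or ``"sharp"`` (pure ramp), plus the raw
    scikit-image filter names.  ``output`` is ``"hu"`` (needs the water
    reference ``mu_water_per_cm``, taken from the sinogram metadata when
    omitted) or ``"mu"`` for raw attenuation in 1/cm.
    """
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {sorted(KERNELS)}")
    geo = sinogram.geometry
    if voxel_mm is None:
        voxel_mm = geo.det_pitch_mm if geo.beam == "parallel" else (
            geo.det_pitch_mm * geo.sid_mm / geo.sdd_mm
        )
    if output_size is None:
        output_size = int(round(geo.fov_mm / voxel_mm))
    if output == "hu":
        if mu_water_per_cm is None:
            mu_water_per_cm = sinogram.mu_water_per_cm
        if mu_water_per_cm is None:
            raise ValueError(
                "HU output needs mu_water_per_cm (pass explicitly or set on the sinogram)"
            )
    elif output != "mu":
        raise ValueError("output must be 'hu' or 'mu'")

    s_out = (np.arange(output_size) - 0.5 * (output_size - 1)) * voxel_mm
    if geo.beam == "fan":
        sinogram = _rebin_fan_to_parallel(sinogram, max(geo.n_views // 2, 180), s_out)
        geo = sinogram.geometry
        s_det = s_out
        vals = sinogram.values
    else:
        s_det = geo.detector_s_mm
        vals = sinogram.values

    theta_deg = np.degrees(geo.view_angles)  # projector angle -> skimage convention
    n_rows = geo.n_rows
    img = np.empty((n_rows, output_size, output_size), dtype=float)
    for j in range(n_rows):
        view_slice = vals[:, :, j]
        if s_det is s_out:
            resampled = view_slice
        else:
            resampled = np.stack(
                [np.interp(s_out, s_det, row, left=0.0, right=0.0) for row in view_slice]
            )
        sk_sino = resampled.T / (voxel_mm / 10.0)  # dimensionless -> per-pixel units
        mu = iradon(
            sk_sino,
            theta=theta_deg,
            output_size=output_size,
            filter_name=KERNELS[kernel],
            circle=False,
        )
        img[j] = mu

    dz = slice_thickness_mm if slice_thickness_mm is not None else voxel_mm
    vol = VoxelVolume(
        data=img,
        spacing_mm=(dz, voxel_mm, voxel_mm),
        is_hu=False,
        meta={"kernel": kernel, "filter": KERNELS[kernel], "beam": sinogram.geometry.beam},
    )
    if output == "mu":
        return vol
    return lac_to_hu(vol, mu_water_per_cm)


# ---------------------------------------------------------------------------

def apply_window(values, window: float, level: float) -> np.ndarray:
    """Linear display window: clamp to [level - W/2, level + W/2], map to [0, 1]."""
    if window <= 0:
        raise ValueError("window width must be positive")
    arr = values.data if isinstance(values, VoxelVolume) else np.asarray(values, dtype=float)
    return np.clip((arr - (level - 0.5 * window)) / window, 0.0, 1.0)
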