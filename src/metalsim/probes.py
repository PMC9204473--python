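"""Digital device models: segmentation, placement, and the probe library.

A :class:`ProbeModel` is a voxelized metallic device stored as an
extended-scale HU volume at a reference tube potential, with a tip
anchor marking the insertion point.  Models are built either
synthetically (see ``phantoms.make_rod_object``) or by segmenting a CT
scan of a real device with thresholding and connectivity filtering.

Placement maps a probe into a target grid by a rigid transform
(in-plane angle, elevation off the axial plane, optional roll about the
device axis) with the tip anchored at a requested world position.
Resampling runs on a 2x supersampled target grid and averages down,
which preserves thin, strongly attenuating substructures better than
single-pass nearest/linear resampling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "ProbeModel",
    "Placement",
    "segment_probe",
    "place_probe",
    "save_probe",
    "load_probe",
    "list_library",
    "converging_placements",
    "parallel_placements",
]

AIR_HU = -1000.0
METAL_SUPPORT_HU = 300.0  # support/segmentation-candidate threshold


@dataclass
class ProbeModel:
    name: str
    hu: np.ndarray  # (nz, ny, nx), extended HU scale
    spacing_mm: tuple[float, float, float]
    reference_kv: float
    tip_voxel: tuple[int, int, int]  # (z, y, x) indices, on the support
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.hu = np.asarray(self.hu, dtype=float)
        if self.hu.ndim != 3:
            raise ValueError("probe volume must be 3-D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("probe voxel spacing must be positive")
        tz, ty, tx = (int(v) for v in self.tip_voxel)
        if not (0 <= tz < self.hu.shape[0] and 0 <= ty < self.hu.shape[1]
                and 0 <= tx < self.hu.shape[2]):
            raise ValueError("tip anchor outside the probe volume")
        self.tip_voxel = (tz, ty, tx)

    def support_mask(self, threshold_hu: float = METAL_SUPPORT_HU) -> np.ndarray:
        return self.hu > threshold_hu

    def support_voxel_count(self, threshold_hu: float = METAL_SUPPORT_HU) -> int:
        return int(self.support_mask(threshold_hu).sum())


@dataclass(frozen=True)
class Placement:
    """Rigid placement of a probe: tip position and orientation.

    ``tip_mm`` is world (x, y, z) with the isocenter at the origin.
    Angles are degrees: ``azimuth`` in-plane about z from +x,
    ``elevation`` off the axial X-Y plane, ``roll`` about the rotated
    x axis.  All angles zero leaves the stored probe orientation
    untouched.
    """

    tip_mm: tuple[float, float, float]
    azimuth_deg: float = 0.0
    elevation_deg: float = 0.0
    roll_deg: float = 0.0

    def __post_init__(self):
        vals = (*self.tip_mm, self.azimuth_deg, self.elevation_deg, self.roll_deg)
        if not np.all(np.isfinite(vals)):
            raise ValueError("placement parameters must be finite")

    def rotation_xyz(self) -> np.ndarray:
        az, el, ro = np.deg2rad([self.azimuth_deg, self.elevation_deg, self.roll_deg])
        ca, sa = np.cos(az), np.sin(az)
        ce, se = np.cos(el), np.sin(el)
        cr, sr = np.cos(ro), np.sin(ro)
        rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        ry = np.array([[ce, 0, se], [0, 1, 0], [-se, 0, ce]])  # Ry(-el): +x lifts toward +z
        rx = np.array([[1, 0, 0], [0, cr, -sr], [0, sr, cr]])
        return rz @ ry @ rx


# ---------------------------------------------------------------------------
# segmentation

def segment_probe(volume, metal_threshold_hu=None, min_component_voxels: int = 10,
                  connectivity: int = 26, bridge_mm: float = 5.0,
                  name: str = "segmented_probe") -> ProbeModel:
    """Extract a metallic device from a CT volume.

    Voxels above the metal threshold (Otsu split of the > 300 HU
    candidates when not given) are grouped by connectivity; components
    below ``min_component_voxels`` are discarded, and surviving
    components within ``bridge_mm`` of each other are treated as one
    device (shaft, coil and handle of a real probe are often separated
    by partial-volume gaps).  The group containing the largest
    component is kept; everything else is zeroed out.
    """
    from .volume import VoxelVolume  # local import to avoid cycles

    if not isinstance(volume, VoxelVolume):
        raise TypeError("segment_probe expects a VoxelVolume in HU")
    data = volume.data
    if metal_threshold_hu is None:
        candidates = data[data > METAL_SUPPORT_HU]
        if candidates.size == 0:
            raise ValueError("no metal found: no voxels above 300 HU")
        from skimage.filters import threshold_otsu
        try:
            otsu = float(threshold_otsu(candidates))
        except ValueError:  # constant candidate values
            otsu = METAL_SUPPORT_HU
        # Otsu only means something when the candidates are bimodal
        # (metal mode vs partial-volume edge mode); on a unimodal metal
        # distribution it would split the metal itself in half.
        lo, hi = candidates[candidates <= otsu], candidates[candidates > otsu]
        if lo.size and hi.size and (
            hi.mean() - lo.mean() > 2.0 * np.hypot(lo.std(), hi.std())
        ):
            metal_threshold_hu = otsu
        else:
            metal_threshold_hu = METAL_SUPPORT_HU
    mask = data > metal_threshold_hu
    if not mask.any():
        raise ValueError(f"no metal found: no voxels above {metal_threshold_hu:g} HU")

    structure = (np.ones((3, 3, 3), bool) if connectivity == 26
                 else ndimage.generate_binary_structure(3, 1))
    labels, n = ndimage.label(mask, structure=structure)
    sizes = np.bincount(labels.ravel())
    keep = np.nonzero(sizes >= min_component_voxels)[0]
    keep = keep[keep != 0]
    if keep.size == 0:
        raise ValueError("no metal found: all components below the minimum size")
    kept_mask = np.isin(labels, keep)

    # bridge nearby components: dilate by bridge_mm/2 and group what touches
    dz, dy, dx = volume.spacing_mm
    it = max(1, int(np.ceil(0.5 * bridge_mm / min(dz, dy, dx))))
    bridged = ndimage.binary_dilation(kept_mask, structure=structure, iterations=it)
    groups, _ = ndimage.label(bridged, structure=structure)
    largest = keep[np.argmax(sizes[keep])]
    group_id = groups[tuple(np.argwhere(labels == largest)[0])]
    device = kept_mask & (groups == group_id)

    # crop with one-voxel margin
    idx = np.argwhere(device)
    lo = np.maximum(idx.min(axis=0) - 1, 0)
    hi = np.minimum(idx.max(axis=0) + 2, device.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    cropped = np.full(tuple(hi - lo), AIR_HU)
    sub = device[sl]
    cropped[sub] = data[sl][sub]

    tip = _tip_anchor(sub, volume.spacing_mm)
    return ProbeModel(
        name=name,
        hu=cropped,
        spacing_mm=volume.spacing_mm,
        reference_kv=float(volume.meta.get("kvp", 120.0)),
        tip_voxel=tuple(int(v) for v in tip),
        meta={"threshold_hu": float(metal_threshold_hu),
              "min_component_voxels": int(min_component_voxels),
              "bridge_mm": float(bridge_mm)},
    )


def _tip_anchor(support: np.ndarray, spacing_mm) -> tuple[int, int, int]:
    """Support voxel most distal along the principal axis.

    The sign of the principal axis is chosen toward the lighter half of
    the device, which is the thin working tip for real probes (the
    handle end is bulkier).
    """
    idx = np.argwhere(support).astype(float)
    pos = idx * np.asarray(spacing_mm)
    center = pos.mean(axis=0)
    centered = pos - center
    if len(idx) == 1:
        return tuple(int(v) for v in idx[0])
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    proj = centered @ axis
    if (proj > 0).sum() > (proj <= 0).sum():
        axis, proj = -axis, -proj
    return tuple(int(v) for v in idx[np.argmax(proj)])


# ---------------------------------------------------------------------------
# placement

def _index_to_world(shape, spacing, origin):
    """Affine (z,y,x index) -> (z,y,x world): w = A i + b."""
    a = np.diag([spacing[0], -spacing[1], spacing[2]])
    return a, np.asarray(origin, dtype=float)


def place_probe(probe: ProbeModel, placement: Placement, target,
                output: str = "hu", spectrum=None, supersample: int = 2,
                clip_warn: bool = True):
    """Resample a probe onto a target grid under a rigid placement.

    ``target`` is a :class:`VoxelVolume` template (only its grid is
    used) or a ``(shape, spacing_mm)`` tuple.  Returns a volume on that
    grid holding the probe contribution: HU with -1000 background, or
    the LAC contribution (``output="lac"``) with zero background.
    Emits a warning with the clipped support fraction when part of the
    device falls outside the grid.
    """
    from .volume import VoxelVolume
    from .physics import effective_mu_water
    from .projector import hu_to_lac
    from .config import default_spectrum

    if output not in ("hu", "lac"):
        raise ValueError("output must be 'hu' or 'lac'")
    if isinstance(target, VoxelVolume):
        t_shape, t_spacing, t_origin = target.shape, target.spacing_mm, target.origin_mm
    else:
        shape, spacing = target
        tmp = VoxelVolume(np.zeros(shape), spacing)
        t_shape, t_spacing, t_origin = tmp.shape, tmp.spacing_mm, tmp.origin_mm

    r_xyz = placement.rotation_xyz()
    perm = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)
    r_zyx = perm @ r_xyz @ perm
    tip_w = np.array([placement.tip_mm[2], placement.tip_mm[1], placement.tip_mm[0]])

    a_p, _ = _index_to_world(probe.hu.shape, probe.spacing_mm, (0, 0, 0))
    hu = _paste_or_resample(probe, r_zyx, tip_w, a_p, t_shape, t_spacing, t_origin,
                            supersample)

    if clip_warn:
        frac = _clipped_fraction(probe, r_zyx, tip_w, a_p, t_shape, t_spacing, t_origin)
        if frac > 1e-6:
            warnings.warn(
                f"probe {probe.name!r} support clipped by target bounds "
                f"({100 * frac:.1f}% outside)"
            )

    vol = VoxelVolume(hu, t_spacing, is_hu=True, origin_mm=t_origin,
                      meta={"probe": probe.name, "reference_kv": probe.reference_kv})
    if output == "hu":
        return vol
    spectrum = spectrum if spectrum is not None else default_spectrum()
    return hu_to_lac(vol, effective_mu_water(spectrum))


def _paste_or_resample(probe, r_zyx, tip_w, a_p, t_shape, t_spacing, t_origin, ss):
    _, b_t = _index_to_world(t_shape, t_spacing, t_origin)
    tip = np.asarray(probe.tip_voxel, dtype=float)

    # fast path: no rotation, identical spacing, integral voxel alignment
    if (np.allclose(r_zyx, np.eye(3), atol=1e-12)
            and np.allclose(probe.spacing_mm, t_spacing)):
        a_t, _ = _index_to_world(t_shape, t_spacing, t_origin)
        tip_idx_t = np.linalg.solve(a_t, tip_w - b_t)  # target index of the tip
        if np.allclose(tip_idx_t, np.round(tip_idx_t), atol=1e-9):
            out = np.full(t_shape, AIR_HU)
            off = np.round(tip_idx_t).astype(int) - probe.tip_voxel
            src_lo = np.maximum(-off, 0)
            src_hi = np.minimum(np.array(probe.hu.shape), np.array(t_shape) - off)
            if np.all(src_hi > src_lo):
                dst_lo = src_lo + off
                dst_hi = src_hi + off
                out[tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))] = \
                    probe.hu[tuple(slice(a, b) for a, b in zip(src_lo, src_hi))]
            return out

    # general path: supersampled rotation + mean-downsampling
    ss_shape = tuple(n * ss for n in t_shape)
    d_s = np.array([t_spacing[0] / ss, t_spacing[1] / ss, t_spacing[2] / ss])
    a_s = np.diag([d_s[0], -d_s[1], d_s[2]])
    # super voxel (0,0,0) center: offset from target voxel (0,0,0) center
    half = (ss - 1) / (2.0 * ss)
    b_s = b_t + np.array([-t_spacing[0] * half, +t_spacing[1] * half, -t_spacing[2] * half])

    r_inv = r_zyx.T
    m = np.linalg.solve(a_p, r_inv @ a_s)
    offset = tip + np.linalg.solve(a_p, r_inv @ (b_s - tip_w))
    sup = ndimage.affine_transform(
        probe.hu, m, offset=offset, output_shape=ss_shape, order=1,
        mode="constant", cval=AIR_HU, prefilter=False,
    )
    return sup.reshape(t_shape[0], ss, t_shape[1], ss, t_shape[2], ss).mean(axis=(1, 3, 5))


def _clipped_fraction(probe, r_zyx, tip_w, a_p, t_shape, t_spacing, t_origin):
    sup_idx = np.argwhere(probe.support_mask())
    if len(sup_idx) == 0:
        return 0.0
    tip = np.asarray(probe.tip_voxel, dtype=float)
    world = (r_zyx @ (a_p @ (sup_idx - tip).T)).T + tip_w
    _, b_t = _index_to_world(t_shape, t_spacing, t_origin)
    a_t = np.diag([t_spacing[0], -t_spacing[1], t_spacing[2]])
    idx_t = np.linalg.solve(a_t, (world - b_t).T).T
    inside = np.all((idx_t > -0.5) & (idx_t < np.array(t_shape) - 0.5), axis=1)
    return 1.0 - inside.mean()


# ---------------------------------------------------------------------------
# library IO

def save_probe(probe: ProbeModel, path) -> None:
    """Write a probe as ``volume.mhd`` (+raw, float) and ``probe.json``."""
    from .io import write_volume
    from .volume import VoxelVolume

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    vol = VoxelVolume(probe.hu, probe.spacing_mm, is_hu=True)
    write_volume(vol, path / "volume.mhd", clamp=False)
    with open(path / "probe.json", "w") as fh:
        json.dump(
            {
                "name": probe.name,
                "spacing_mm": list(probe.spacing_mm),
                "reference_kv": probe.reference_kv,
                "tip_voxel": list(probe.tip_voxel),
                "meta": probe.meta,
            },
            fh, indent=2,
        )


def load_probe(path) -> ProbeModel:
    from .io import read_volume

    path = Path(path)
    meta_path = path / "probe.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"{path} is not a probe directory (no probe.json)")
    with open(meta_path) as fh:
        d = json.load(fh)
    for key in ("name", "spacing_mm", "reference_kv", "tip_voxel"):
        if key not in d:
            raise ValueError(f"probe.json is missing required field {key!r}")
    vol = read_volume(path / "volume.mhd")
    return ProbeModel(
        name=d["name"],
        hu=vol.data,
        spacing_mm=tuple(d["spacing_mm"]),
        reference_kv=float(d["reference_kv"]),
        tip_voxel=tuple(int(v) for v in d["tip_voxel"]),
        meta=d.get("meta", {}),
    )


def list_library(path) -> list[str]:
    """Names of the probes stored in a library directory."""
    path = Path(path)
    return sorted(p.parent.name for p in path.glob("*/probe.json"))


# ---------------------------------------------------------------------------
# multi-probe placement generators

def converging_placements(target_mm, n: int, elevation_deg: float = 0.0,
                          start_azimuth_deg: float = 0.0,
                          spread_deg: float = 180.0) -> list[Placement]:
    """Placements whose tips meet at a common target point.

    Approach azimuths are spread evenly over ``spread_deg``.
    """
    if n < 1:
        raise ValueError("need at least one probe")
    azimuths = start_azimuth_deg + np.arange(n) * (spread_deg / max(n, 1))
    return [Placement(tip_mm=tuple(target_mm), azimuth_deg=float(a),
                      elevation_deg=elevation_deg) for a in azimuths]


def parallel_placements(tips_mm, azimuth_deg: float = 0.0,
                        elevation_deg: float = 0.0) -> list[Placement]:
    """Placements sharing one orientation with individual tip offsets."""
    return [Placement(tip_mm=tuple(t), azimuth_deg=azimuth_deg,
                      elevation_deg=elevation_deg) for t in tips_mm]
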