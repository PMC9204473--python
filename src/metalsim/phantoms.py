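"""Digital phantoms.

Water-equivalent discs and ellipses with cylindrical inserts, plus
free-standing voxelized rods, mirroring the quality-assurance phantoms
used to validate the insertion physics: a 20-cm circular head phantom,
a 30 x 40 cm elliptical body phantom, and a 12.7-mm solid titanium rod
in the central hole.

Voxels are assigned by center-point membership (no antialiasing);
multi-slice phantoms are extruded 2-D sections.  CT numbers come from
the packaged material tables evaluated under the reference spectrum, so
water is exactly 0 HU and air outside the support is -1000 HU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .config import default_spectrum
from .materials import available_materials, load_material
from .physics import material_hu
from .probes import ProbeModel
from .volume import VoxelVolume

__all__ = [
    "CylinderInsert",
    "PhantomSpec",
    "make_disc_phantom",
    "make_ellipse_phantom",
    "make_rod_object",
]

AIR_HU = -1000.0
DEFAULT_AIR_MARGIN = 0.10  # fraction of the largest dimension, per side


@dataclass(frozen=True)
class CylinderInsert:
    """Axially extruded cylindrical insert (axis along z)."""

    center_mm: tuple[float, float]  # world (x, y)
    diameter_mm: float
    material: str
    axis: str = "z"

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("insert diameter must be positive")
        if self.axis != "z":
            raise ValueError("inserts are extruded along z; axis must be 'z'")


@dataclass(frozen=True)
class PhantomSpec:
    """Serializable description of a phantom build."""

    shape: str  # "disc" | "ellipse"
    dimensions_mm: tuple  # (diameter,) or (axis_y, axis_x)
    background_material: str = "water"
    inserts: tuple = ()
    voxel_mm: float = 1.0
    n_slices: int = 1
    grid_shape: tuple[int, int] | None = None
    air_margin: float = DEFAULT_AIR_MARGIN

    def build(self, spectrum=None) -> VoxelVolume:
        if self.shape == "disc":
            return make_disc_phantom(
                self.dimensions_mm[0], self.background_material, self.inserts,
                self.voxel_mm, self.n_slices, grid_shape=self.grid_shape,
                air_margin=self.air_margin, spectrum=spectrum,
            )
        if self.shape == "ellipse":
            return make_ellipse_phantom(
                tuple(self.dimensions_mm), self.background_material, self.inserts,
                self.voxel_mm, self.n_slices, grid_shape=self.grid_shape,
                air_margin=self.air_margin, spectrum=spectrum,
            )
        raise ValueError(f"unknown phantom shape {self.shape!r}")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["inserts"] = [asdict(i) for i in self.inserts]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            d = json.load(fh)
        d["inserts"] = tuple(CylinderInsert(**{**i, "center_mm": tuple(i["center_mm"])})
                             for i in d.get("inserts", []))
        d["dimensions_mm"] = tuple(d["dimensions_mm"])
        if d.get("grid_shape"):
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


def _check_material(name: str) -> None:
    if name not in available_materials():
        raise KeyError(
            f"unknown material {name!r}; available: {', '.join(available_materials())}"
        )


def _grid(extent_x: float, extent_y: float, voxel_mm: float, air_margin: float,
          grid_shape):
    if voxel_mm <= 0:
        raise ValueError("voxel spacing must be positive")
    if grid_shape is not None:
        ny, nx = grid_shape
    else:
        margin = air_margin * max(extent_x, extent_y)
        nx = int(np.ceil((extent_x + 2 * margin) / voxel_mm))
        ny = int(np.ceil((extent_y + 2 * margin) / voxel_mm))
        nx += nx % 2
        ny += ny % 2
    x = (np.arange(nx) - 0.5 * (nx - 1)) * voxel_mm
    y = (0.5 * (ny - 1) - np.arange(ny)) * voxel_mm  # +y up
    return np.meshgrid(x, y, indexing="xy"), (ny, nx)


def _paint(support, X, Y, background_material, inserts, n_slices, voxel_mm, spectrum,
           inside_fn):
    spectrum = spectrum if spectrum is not None else default_spectrum()
    hu2d = np.full(support.shape, AIR_HU)
    hu2d[support] = material_hu(background_material, spectrum)
    for ins in inserts:
        ins = ins if isinstance(ins, CylinderInsert) else CylinderInsert(**ins)
        _check_material(ins.material)
        cx, cy = ins.center_mm
        r = 0.5 * ins.diameter_mm
        if not inside_fn(cx, cy, r):
            raise ValueError(
                f"insert {ins.material!r} at ({cx}, {cy}) mm with diameter "
                f"{ins.diameter_mm} mm does not fit inside the phantom support"
            )
        mask = (X - cx) ** 2 + (Y - cy) ** 2 <= r**2
        hu2d[mask] = material_hu(ins.material, spectrum)
    data = np.repeat(hu2d[None, :, :], n_slices, axis=0)
    return VoxelVolume(
        data, (voxel_mm, voxel_mm, voxel_mm), is_hu=True,
        meta={"kvp": spectrum.kvp},
    )


def make_disc_phantom(diameter_mm, background_material="water", inserts=(),
                      voxel_mm=1.0, n_slices=1, grid_shape=None,
                      air_margin=DEFAULT_AIR_MARGIN, spectrum=None) -> VoxelVolume:
    """Circular water-equivalent phantom (head-phantom analog)."""
    if diameter_mm <= 0:
        raise ValueError("phantom diameter must be positive")
    _check_material(background_material)
    (X, Y), _ = _grid(diameter_mm, diameter_mm, voxel_mm, air_margin, grid_shape)
    R = 0.5 * diameter_mm
    support = X**2 + Y**2 <= R**2

    def inside(cx, cy, r):
        return np.hypot(cx, cy) + r <= R + 1e-9

    return _paint(support, X, Y, background_material, inserts, n_slices, voxel_mm,
                  spectrum, inside)


def make_ellipse_phantom(axes_mm=(300.0, 400.0), background_material="water",
                         inserts=(), voxel_mm=1.0, n_slices=1, grid_shape=None,
                         air_margin=DEFAULT_AIR_MARGIN, spectrum=None) -> VoxelVolume:
    """Elliptical body-phantom analog.

    ``axes_mm`` is (vertical extent, horizontal extent): the default
    emulates a 30 cm anterior-posterior by 40 cm lateral body section.
    """
    ay, ax = float(axes_mm[0]), float(axes_mm[1])
    if ay <= 0 or ax <= 0:
        raise ValueError("ellipse axes must be positive")
    _check_material(background_material)
    (X, Y), _ = _grid(ax, ay, voxel_mm, air_margin, grid_shape)
    rx, ry = 0.5 * ax, 0.5 * ay
    support = (X / rx) ** 2 + (Y / ry) ** 2 <= 1.0

    def inside(cx, cy, r):
        # conservative: shrink both semi-axes by the insert radius
        if r >= min(rx, ry):
            return False
        return (cx / (rx - r)) ** 2 + (cy / (ry - r)) ** 2 <= 1.0 + 1e-9

    return _paint(support, X, Y, background_material, inserts, n_slices, voxel_mm,
                  spectrum, inside)


def make_rod_object(diameter_mm, length_mm, material="titanium", voxel_mm=0.5,
                    orientation=(0.0, 90.0), spectrum=None, name=None) -> ProbeModel:
    """Voxelized solid cylinder in its own local frame.

    ``orientation`` is (azimuth_deg, elevation_deg) of the rod axis:
    elevation is measured off the axial X-Y plane (90 deg = along z,
    the extruded-slice direction; 26 deg = the oblique water-tank
    setup), azimuth about z from +x.  The tip anchor sits at the +axis
    end.
    """
    if diameter_mm <= 0 or length_mm <= 0:
        raise ValueError("rod diameter and length must be positive")
    if voxel_mm <= 0:
        raise ValueError("voxel spacing must be positive")
    _check_material(material)
    spectrum = spectrum if spectrum is not None else default_spectrum()

    az, el = np.deg2rad(orientation[0]), np.deg2rad(orientation[1])
    d = np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])  # (x,y,z)
    half = 0.5 * length_mm
    r = 0.5 * diameter_mm
    # bounding box of the finite cylinder, one-voxel margin
    ext = np.abs(d) * half + r + voxel_mm
    n = np.maximum(np.ceil(2 * ext / voxel_mm).astype(int) + 1, 3)  # (nx, ny, nz)
    xs = (np.arange(n[0]) - 0.5 * (n[0] - 1)) * voxel_mm
    ys = (0.5 * (n[1] - 1) - np.arange(n[1])) * voxel_mm
    zs = (np.arange(n[2]) - 0.5 * (n[2] - 1)) * voxel_mm
    Z, Yv, Xv = np.meshgrid(zs, ys, xs, indexing="ij")
    P = np.stack([Xv, Yv, Z], axis=-1)
    t = P @ d
    radial2 = np.sum(P * P, axis=-1) - t**2
    mask = (np.abs(t) <= half) & (radial2 <= r**2)
    if not mask.any():
        raise ValueError("rod dimensions are below the voxel size; nothing rasterized")

    hu = np.full(mask.shape, AIR_HU)
    hu[mask] = material_hu(material, spectrum)
    # tip anchor: support voxel closest to the +axis end of the cylinder
    idx = np.argwhere(mask)
    tip_world = d * half
    pos = np.stack([Xv[mask], Yv[mask], Z[mask]], axis=-1)
    tip_voxel = tuple(int(v) for v in idx[np.argmin(np.sum((pos - tip_world) ** 2, axis=1))])
    return ProbeModel(
        name=name or f"{material}_rod_{diameter_mm:g}x{length_mm:g}mm",
        hu=hu,
        spacing_mm=(voxel_mm, voxel_mm, voxel_mm),
        reference_kv=spectrum.kvp,
        tip_voxel=tip_voxel,
        meta={"material": material, "diameter_mm": diameter_mm, "length_mm": length_mm,
              "orientation_deg": tuple(float(a) for a in orientation)},
    )
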