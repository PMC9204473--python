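"""File IO: volumes (MetaImage / NIfTI), sinograms (HDF5), spectra (CSV).

HU volumes are clamped on write to the standard 12-bit CT range
[-1024, 3071] unless the extended 16-bit scale is requested
([-10240, 30710]), mirroring scanner export behavior; ``clamp=False``
writes raw float values (used by the probe library, which must
round-trip losslessly).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import SimpleITK as sitk

from .geometry import AcquisitionGeometry
from .projector import Sinogram
from .volume import VoxelVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_sinogram",
    "write_sinogram",
    "HU_RANGE_STANDARD",
    "HU_RANGE_EXTENDED",
]

HU_RANGE_STANDARD = (-1024.0, 3071.0)
HU_RANGE_EXTENDED = (-10240.0, 30710.0)


def write_volume(volume: VoxelVolume, path, clamp: bool = True,
                 extended_hu: bool = False) -> None:
    """Write a volume as .mhd/.raw or .nii/.nii.gz (by extension)."""
    data = volume.data
    if clamp and volume.is_hu:
        lo, hi = HU_RANGE_EXTENDED if extended_hu else HU_RANGE_STANDARD
        data = np.clip(data, lo, hi)
    img = sitk.GetImageFromArray(data.astype(np.float32))
    dz, dy, dx = volume.spacing_mm
    img.SetSpacing((dx, dy, dz))
    oz, oy, ox = volume.origin_mm
    img.SetOrigin((ox, oy, oz))
    img.SetMetaData("metalsim_is_hu", "1" if volume.is_hu else "0")
    sitk.WriteImage(img, str(path))


def read_volume(path) -> VoxelVolume:
    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img).astype(float)
    if data.ndim == 2:
        data = data[None]
    sx, sy, sz = (list(img.GetSpacing()) + [1.0, 1.0])[:3]
    ox, oy, oz = (list(img.GetOrigin()) + [0.0, 0.0])[:3]
    is_hu = True
    if img.HasMetaDataKey("metalsim_is_hu"):
        is_hu = img.GetMetaData("metalsim_is_hu") == "1"
    return VoxelVolume(data, (sz, sy, sx), is_hu=is_hu, origin_mm=(oz, oy, ox))


def write_sinogram(sino: Sinogram, path) -> None:
    """HDF5 layout: dataset ``P`` (views x cols x rows), optional ``N0``,
    geometry and tube potential as root attributes."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("P", data=sino.values)
        if sino.n0 is not None:
            fh.create_dataset("N0", data=np.asarray(sino.n0, dtype=float))
        for key, val in sino.geometry.to_dict().items():
            if val is not None:
                fh.attrs[f"geometry_{key}"] = val
        if sino.kvp is not None:
            fh.attrs["kvp"] = sino.kvp
        if sino.mu_water_per_cm is not None:
            fh.attrs["mu_water_per_cm"] = sino.mu_water_per_cm
        for key, val in sino.meta.items():
            if isinstance(val, (str, int, float, bool)):
                fh.attrs[f"meta_{key}"] = val


def read_sinogram(path) -> Sinogram:
    with h5py.File(path, "r") as fh:
        values = fh["P"][()]
        n0 = fh["N0"][()] if "N0" in fh else None
        if n0 is not None and n0.ndim == 0:
            n0 = float(n0)
        geo_kwargs = {}
        meta = {}
        for key, val in fh.attrs.items():
            if key.startswith("geometry_"):
                geo_kwargs[key[len("geometry_"):]] = val
            elif key.startswith("meta_"):
                meta[key[len("meta_"):]] = val
        if "beam" in geo_kwargs:
            geo_kwargs["beam"] = str(geo_kwargs["beam"])
        for k in ("n_views", "n_cols", "n_rows"):
            if k in geo_kwargs:
                geo_kwargs[k] = int(geo_kwargs[k])
        for k in ("det_pitch_mm", "fov_mm", "angular_range", "sid_mm", "sdd_mm"):
            if k in geo_kwargs:
                geo_kwargs[k] = float(geo_kwargs[k])
        geometry = AcquisitionGeometry(**geo_kwargs)
        return Sinogram(
            values=values,
            geometry=geometry,
            kvp=float(fh.attrs["kvp"]) if "kvp" in fh.attrs else None,
            n0=n0,
            mu_water_per_cm=(float(fh.attrs["mu_water_per_cm"])
                             if "mu_water_per_cm" in fh.attrs else None),
            meta=meta,
        )
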