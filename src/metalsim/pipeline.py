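"""End-to-end insertion pipeline.

Orchestrates the projection-domain insertion chain: place probes, sum
their attenuation, forward project, apply the beam-hardening scaling
and the metal noise element, and add the result to the original
projections.  Also provides the artifact-free image-domain insertion
and the generation of coregistered training pairs (projection-domain
input with artifacts, image-domain target without).

Pipeline order is fixed: beam hardening first, then noise.  The noise
standard deviation is evaluated with the hardening-corrected metal
projection, since that is the better estimate of the actually
transmitted flux; the metal-ray mask is always derived from the
uncorrected projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

import metalsim

from .config import DEFAULT_NE, default_spectrum, n0_for_eff_mas
from .geometry import AcquisitionGeometry
from .noise import NoiseParams, sample_acquisition_noise, sample_metal_noise
from .physics import beam_hardening_correct, compute_ray_physics, effective_mu_water
from .probes import Placement, ProbeModel, place_probe
from .projector import Sinogram, fbp_reconstruct, forward_project, hu_to_lac
from .spectrum import Spectrum
from .volume import VoxelVolume

__all__ = [
    "InsertionRun",
    "scan_phantom",
    "insert_projection_domain",
    "insert_image_domain",
    "make_training_pair",
]

METAL_MASK_HU = 500.0  # metal-mask threshold for coregistration reports


@dataclass
class InsertionRun:
    """Configuration of one projection-domain insertion.

    The physics toggles are independent so each model's effect can be
    isolated; the provenance log returned with the combined sinogram
    records every parameter needed to replay the run bit-exactly.
    """

    probes: list[tuple[ProbeModel, Placement]]
    spectrum: Spectrum | None = None
    bh_on: bool = True
    noise_on: bool = True
    noise: NoiseParams | None = None
    seed: int = 0
    reference_material: str = "titanium"
    allow_clip: bool = False

    def resolved_spectrum(self) -> Spectrum:
        return self.spectrum if self.spectrum is not None else default_spectrum()


def scan_phantom(volume: VoxelVolume, geometry: AcquisitionGeometry,
                 spectrum: Spectrum | None = None, n0: float | None = None,
                 ne: float = DEFAULT_NE, seed: int | None = None) -> Sinogram:
    """Simulate an acquisition of an HU phantom.

    Converts to attenuation with the spectrum's effective water LAC,
    forward projects, and (when ``n0`` is given) adds measurement noise
    so the baseline sinogram behaves like real, already-noisy data.
    """
    spectrum = spectrum if spectrum is not None else default_spectrum()
    mu_w = effective_mu_water(spectrum)
    lac = volume if not volume.is_hu else hu_to_lac(volume, mu_w)
    sino = forward_project(lac, geometry)
    sino.kvp = spectrum.kvp
    sino.n0 = n0
    if n0 is not None:
        rng = np.random.default_rng(seed)
        sino.values = sample_acquisition_noise(sino.values, n0, ne, rng)
        np.clip(sino.values, 0.0, None, out=sino.values)
    return sino


def _grid_template(geometry: AcquisitionGeometry, grid) -> VoxelVolume:
    if isinstance(grid, VoxelVolume):
        if grid.shape[0] != geometry.n_rows:
            raise ValueError(
                f"grid has {grid.shape[0]} slices but geometry expects {geometry.n_rows}"
            )
        return grid
    shape, spacing = grid
    return VoxelVolume(np.zeros(shape), spacing)


def insert_projection_domain(original: Sinogram, run: InsertionRun, grid,
                             return_diagnostics: bool = False):
    """Combine probe projections with an original sinogram.

    ``grid`` (a :class:`VoxelVolume` template or ``(shape, spacing)``)
    defines the grid on which probes are voxelized before forward
    projection; its slice count must match the sinogram's detector
    rows.  Returns the combined sinogram with a provenance log in its
    ``meta``; with ``return_diagnostics=True`` also returns a dict with
    the clean metal projection, the corrected one, the noise field and
    the per-ray physics.
    """
    spectrum = run.resolved_spectrum()
    geometry = original.geometry
    template = _grid_template(geometry, grid)
    mu_w = effective_mu_water(spectrum)

    lac_sum = np.zeros(template.shape)
    for probe, placement in run.probes:
        contrib = place_probe(probe, placement, template, output="lac",
                              spectrum=spectrum, clip_warn=not run.allow_clip)
        lac_sum += contrib.data
    lac_vol = template.like(lac_sum, is_hu=False, meta={"mu_water_per_cm": mu_w})

    p_metal = forward_project(lac_vol, geometry,
                              allow_truncation=run.allow_clip).values
    por = original.values

    p_corrected = p_metal
    ray_physics = None
    if run.bh_on and any(p.support_voxel_count() for p, _ in run.probes):
        ray_physics = compute_ray_physics(por, p_metal, spectrum,
                                          reference_material=run.reference_material)
        p_corrected = beam_hardening_correct(p_metal, ray_physics)

    noise_field = np.zeros_like(p_metal)
    params = run.noise if run.noise is not None else NoiseParams(
        n0=original.n0 if original.n0 is not None else n0_for_eff_mas(),
        ne=DEFAULT_NE,
    )
    if run.noise_on:
        rng = np.random.default_rng(run.seed)
        noise_field = sample_metal_noise(p_corrected, por, params, rng)

    combined = Sinogram(
        values=por + p_corrected + noise_field,
        geometry=geometry,
        kvp=spectrum.kvp,
        n0=original.n0,
        mu_water_per_cm=mu_w,
        meta={**original.meta, "provenance": _provenance(run, original, params)},
    )
    if return_diagnostics:
        return combined, {
            "p_metal": p_metal,
            "p_metal_corrected": p_corrected,
            "noise": noise_field,
            "ray_physics": ray_physics,
        }
    return combined


def _provenance(run: InsertionRun, original: Sinogram, params: NoiseParams) -> dict:
    spectrum = run.resolved_spectrum()
    return {
        "package_version": metalsim.__version__,
        "seed": int(run.seed),
        "bh_on": bool(run.bh_on),
        "noise_on": bool(run.noise_on),
        "n0": (params.n0.tolist() if isinstance(params.n0, np.ndarray)
               else float(params.n0)),
        "ne": float(params.ne),
        "reference_material": run.reference_material,
        "spectrum": {"kvp": spectrum.kvp, **spectrum.meta},
        "geometry": original.geometry.to_dict(),
        "probes": [
            {
                "name": probe.name,
                "reference_kv": probe.reference_kv,
                "tip_mm": list(placement.tip_mm),
                "azimuth_deg": placement.azimuth_deg,
                "elevation_deg": placement.elevation_deg,
                "roll_deg": placement.roll_deg,
            }
            for probe, placement in run.probes
        ],
    }


def run_from_provenance(provenance: dict, probe_lookup) -> InsertionRun:
    """Rebuild an :class:`InsertionRun` from a provenance log.

    ``probe_lookup`` maps probe names to :class:`ProbeModel` objects
    (e.g. a dict, or ``load_probe`` results keyed by name).  Replaying
    the rebuilt run against the same original sinogram reproduces the
    combined sinogram bit-exactly.
    """
    probes = [
        (
            probe_lookup[p["name"]],
            Placement(tip_mm=tuple(p["tip_mm"]), azimuth_deg=p["azimuth_deg"],
                      elevation_deg=p["elevation_deg"], roll_deg=p["roll_deg"]),
        )
        for p in provenance["probes"]
    ]
    from .spectrum import generate_spectrum
    spec_meta = provenance["spectrum"]
    spectrum = (generate_spectrum(spec_meta["kvp"], spec_meta["filtration_mm_al"])
                if spec_meta.get("model") == "filtered_kramers" else None)
    n0 = provenance["n0"]
    return InsertionRun(
        probes=probes,
        spectrum=spectrum,
        bh_on=provenance["bh_on"],
        noise_on=provenance["noise_on"],
        noise=NoiseParams(n0=np.asarray(n0) if isinstance(n0, list) else n0,
                          ne=provenance["ne"]),
        seed=provenance["seed"],
        reference_material=provenance["reference_material"],
    )


# ---------------------------------------------------------------------------
# image domain

def insert_image_domain(volume: VoxelVolume,
                        probes_with_placements,
                        spectrum: Spectrum | None = None) -> VoxelVolume:
    """Artifact-free insertion: composite probe HU into the image.

    Voxelwise max-compositing paints each probe onto the volume;
    everything outside the probe supports is untouched (bit-exactly),
    and overlapping probes resolve to the larger HU value.
    """
    out = volume.copy()
    for probe, placement in probes_with_placements:
        contrib = place_probe(probe, placement, volume, output="hu",
                              spectrum=spectrum)
        np.maximum(out.data, contrib.data, out=out.data)
    return out


# ---------------------------------------------------------------------------
# training pairs

@dataclass
class CoregistrationReport:
    dice: float
    centroid_offset_mm: float | None
    components_input: int
    components_target: int
    threshold_hu: float
    passed: bool
    details: dict = field(default_factory=dict)


def make_training_pair(volume: VoxelVolume, probes, placements,
                       geometry: AcquisitionGeometry,
                       spectrum: Spectrum | None = None,
                       kernel: str = "smooth",
                       bh_on: bool = True, noise_on: bool = True,
                       n0: float | None = None, ne: float = DEFAULT_NE,
                       seed: int = 0, dice_floor: float = 0.8,
                       threshold_hu: float = METAL_MASK_HU,
                       min_component_voxels: int = 5):
    """Coregistered (artifact, artifact-free) image pair for one scene.

    The input image comes from projection-domain insertion into the
    simulated scan of ``volume`` followed by reconstruction on the same
    grid; the target comes from image-domain insertion with identical
    placements.  The report quantifies coregistration by the Dice
    overlap of the metal masks (``threshold_hu``) and the centroid
    offset in mm; a Dice below ``dice_floor`` flags the pair as failed.
    """
    from .metrics import dice_overlap

    if volume.shape[1] != volume.shape[2]:
        raise ValueError("training pairs need a square in-plane grid")
    probes_with_placements = list(zip(probes, placements, strict=True))
    spectrum = spectrum if spectrum is not None else default_spectrum()

    if not probes_with_placements:
        # nothing to insert: both members are the unmodified volume
        report = CoregistrationReport(
            dice=1.0, centroid_offset_mm=None, components_input=0,
            components_target=0, threshold_hu=float(threshold_hu), passed=True,
            details={"note": "no probes; Dice of two empty masks is 1 by convention"},
        )
        return volume.copy(), volume.copy(), report

    target = insert_image_domain(volume, probes_with_placements, spectrum)

    original = scan_phantom(volume, geometry, spectrum,
                            n0=n0 if noise_on else None, ne=ne, seed=seed + 1)
    if original.n0 is None:
        original.n0 = n0
    run = InsertionRun(
        probes=probes_with_placements, spectrum=spectrum, bh_on=bh_on,
        noise_on=noise_on and n0 is not None,
        noise=NoiseParams(n0=n0, ne=ne) if n0 is not None else None,
        seed=seed,
    )
    combined = insert_projection_domain(original, run, volume)
    recon = fbp_reconstruct(
        combined, kernel=kernel, output_size=volume.shape[2],
        voxel_mm=volume.spacing_mm[2], slice_thickness_mm=volume.spacing_mm[0],
    )
    recon.meta["provenance"] = combined.meta.get("provenance")

    mask_in = recon.data > threshold_hu
    mask_tg = target.data > threshold_hu
    dice = dice_overlap(recon, target, threshold_hu)
    if probes_with_placements and mask_in.any() and mask_tg.any():
        sp = np.array([volume.spacing_mm[0], volume.spacing_mm[1], volume.spacing_mm[2]])
        c_in = np.array(ndimage.center_of_mass(mask_in)) * sp
        c_tg = np.array(ndimage.center_of_mass(mask_tg)) * sp
        offset = float(np.linalg.norm(c_in - c_tg))
    else:
        offset = None
    def _n_components(mask):
        # metal components; speckle below the minimum size is counting noise
        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
        if n == 0:
            return 0
        sizes = np.bincount(labels.ravel())[1:]
        return int((sizes >= min_component_voxels).sum())

    report = CoregistrationReport(
        dice=float(dice),
        centroid_offset_mm=offset,
        components_input=_n_components(mask_in),
        components_target=_n_components(mask_tg),
        threshold_hu=float(threshold_hu),
        passed=bool(dice >= dice_floor),
        details={"kernel": kernel, "bh_on": bh_on, "noise_on": noise_on,
                 "seed": seed, "n0": n0, "ne": ne},
    )
    return recon, target, report
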