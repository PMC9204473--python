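"""Beam-hardening physics.

The beam-hardening correction rests on three quantities, computed per
ray of the sinogram:

* the water-equivalent path WEP, the thickness of water whose
  polychromatic attenuation equals the ray's total line integral
  (object plus inserted metal);
* the hardened spectrum reaching the detector after that water
  thickness;
* the effective mass attenuation coefficient of the reference metal
  (titanium by default), i.e. the spectrum-weighted mean of its
  tabulated mu/rho.

Metal projections are then rescaled by mu_m / mu_m_ave, the ratio of
each ray's effective coefficient to the average over all rays that
intersect the metal.  Only this ratio enters the correction, so it is
insensitive to the absolute normalization of the spectrum model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .materials import MaterialTable, load_material
from .spectrum import Spectrum

__all__ = [
    "RayPhysics",
    "polychromatic_projection",
    "compute_wep",
    "harden_spectrum",
    "effective_mass_attenuation",
    "effective_mu_water",
    "material_hu",
    "compute_ray_physics",
    "beam_hardening_correct",
]

METAL_RAY_THRESHOLD = 1e-6  # dimensionless line-integral units
WEP_TOLERANCE = 1e-6


def _water(material=None) -> MaterialTable:
    return load_material("water") if material is None else material


def polychromatic_projection(thickness_cm, spectrum: Spectrum, material=None):
    """Line integral -ln(transmission) of ``thickness_cm`` of water.

    Accepts scalars or arrays.  The transmission is averaged over the
    detected spectrum (fluence x detector weight), which is what a CT
    detector records.
    """
    mat = _water(material)
    t = np.asarray(thickness_cm, dtype=float)
    if np.any(t < 0):
        raise ValueError("thickness must be nonnegative")
    mu = mat.mu(spectrum.energies_keV)  # 1/cm
    w = spectrum.weights
    trans = np.exp(-mu * t[..., None]) @ w
    out = -np.log(trans)
    return float(out) if np.isscalar(thickness_cm) else out


def compute_wep(p_total, spectrum: Spectrum, material=None, tol: float = WEP_TOLERANCE):
    """Water-equivalent path (cm) for dimensionless line integrals.

    Inverts the polychromatic attenuation curve of water by bracketed
    bisection, vectorized over ``p_total``; the returned thickness
    satisfies ``|P(WEP) - p_total| < tol``.  The curve is strictly
    increasing so the root is unique.
    """
    mat = _water(material)
    p = np.asarray(p_total, dtype=float)
    if np.any(p < 0):
        raise ValueError("line integrals must be nonnegative")
    mu = mat.mu(spectrum.energies_keV)
    w = spectrum.weights

    def forward(t):
        return -np.log(np.exp(-np.outer(t, mu)) @ w)

    flat = p.reshape(-1)
    # upper bracket: hardened attenuation is sub-linear, so p / mu_min bounds t
    hi0 = float(np.max(flat, initial=0.0) / mu.min() + 1.0)
    lo = np.zeros_like(flat)
    hi = np.full_like(flat, hi0)
    # bisection on P(t); ~64 halvings reach machine-level bracket width
    for _ in range(90):
        mid = 0.5 * (lo + hi)
        take_hi = forward(mid) > flat
        hi = np.where(take_hi, mid, hi)
        lo = np.where(take_hi, lo, mid)
        if np.max(hi - lo) < 1e-12:
            break
    t = 0.5 * (lo + hi)
    t[flat == 0] = 0.0
    if np.max(np.abs(forward(t) - flat)) >= tol:
        raise RuntimeError("WEP inversion did not converge")
    return float(t[0]) if np.isscalar(p_total) or p.ndim == 0 else t.reshape(p.shape)


def harden_spectrum(spectrum: Spectrum, wep_cm: float, material=None) -> Spectrum:
    """Spectrum recorded after ``wep_cm`` of water.

    The fluence is multiplied by the detector weighting and the water
    transmission and renormalized; the returned spectrum carries a unit
    detector weight because the detector response is already folded in.
    """
    if wep_cm < 0:
        raise ValueError("water-equivalent path must be nonnegative")
    mat = _water(material)
    mu = mat.mu(spectrum.energies_keV)
    w = spectrum.fluence * spectrum.detector_weight * np.exp(-mu * wep_cm)
    return replace(
        spectrum,
        fluence=w / w.sum(),
        detector_weight=np.ones_like(w),
        meta={**spectrum.meta, "hardened_by_cm_water": float(wep_cm)},
    )


def effective_mass_attenuation(material, spectrum: Spectrum) -> float:
    """Spectrum-weighted effective mu/rho (cm^2/g) of ``material``."""
    if isinstance(material, str):
        material = load_material(material)
    mu_rho = material.mu_over_rho(spectrum.energies_keV)
    return float(np.sum(mu_rho * spectrum.weights))


def effective_mu_water(spectrum: Spectrum) -> float:
    """Effective linear attenuation of water (1/cm) under ``spectrum``.

    This is the reference value used for HU <-> LAC conversion
    throughout the monochromatic-equivalent simulation chain.
    """
    w = load_material("water")
    return effective_mass_attenuation(w, spectrum) * w.density_g_cm3


def material_hu(material, spectrum: Spectrum) -> float:
    """CT number (HU, extended scale) of a material under ``spectrum``."""
    if isinstance(material, str):
        material = load_material(material)
    mu = effective_mass_attenuation(material, spectrum) * material.density_g_cm3
    mu_w = effective_mu_water(spectrum)
    return 1000.0 * (mu - mu_w) / mu_w


@dataclass(frozen=True)
class RayPhysics:
    """Per-ray beam-hardening quantities for one insertion.

    ``wep_cm`` and ``mu_m`` are defined (nonzero) on the metal-ray mask
    only; ``mu_m_ave`` is the unweighted arithmetic mean of ``mu_m``
    over that mask.
    """

    wep_cm: np.ndarray
    mu_m: np.ndarray
    mu_m_ave: float
    mask: np.ndarray

    def __post_init__(self):
        if np.any(self.wep_cm < 0):
            raise ValueError("WEP must be nonnegative")
        if self.mask.any() and self.mu_m_ave <= 0:
            raise ValueError("average mass attenuation must be positive")


def compute_ray_physics(
    p_original,
    p_metal,
    spectrum: Spectrum,
    reference_material="titanium",
    mask_threshold: float = METAL_RAY_THRESHOLD,
) -> RayPhysics:
    """WEP, per-ray effective mu_m and mu_m_ave for an insertion.

    The WEP is computed from the TOTAL attenuation (original object plus
    inserted metal), because the hardened spectrum that the detector
    would record has traversed both.  Rays are considered metal rays
    when their clean metal projection exceeds ``mask_threshold``.
    """
    por = np.asarray(p_original, dtype=float)
    pm = np.asarray(p_metal, dtype=float)
    if por.shape != pm.shape:
        raise ValueError("original and metal projections must have the same shape")
    if isinstance(reference_material, str):
        reference_material = load_material(reference_material)
    water = load_material("water")
    mask = pm > mask_threshold

    wep = np.zeros_like(pm)
    mu_m = np.zeros_like(pm)
    mu_m_ave = 0.0
    if mask.any():
        wep_masked = compute_wep(por[mask] + pm[mask], spectrum, material=water)
        wep[mask] = wep_masked
        # hardened weights per masked ray, vectorized over rays x energies
        mu_w = water.mu(spectrum.energies_keV)
        mu_ref = reference_material.mu_over_rho(spectrum.energies_keV)
        w0 = spectrum.fluence * spectrum.detector_weight
        w_hard = w0[None, :] * np.exp(-np.outer(wep_masked, mu_w))
        w_hard /= w_hard.sum(axis=1, keepdims=True)
        mu_m[mask] = w_hard @ mu_ref
        mu_m_ave = float(mu_m[mask].mean())
    return RayPhysics(wep_cm=wep, mu_m=mu_m, mu_m_ave=mu_m_ave, mask=mask)


def beam_hardening_correct(p_metal, ray_physics: RayPhysics):
    """Scale metal projections by mu_m / mu_m_ave on the metal-ray mask.

    Off-mask rays pass through unchanged.  An empty mask (no metal in
    the beam) returns the input unchanged with a warning.
    """
    pm = np.asarray(p_metal, dtype=float)
    if pm.shape != ray_physics.mask.shape:
        raise ValueError("projection and ray-physics shapes differ")
    if not ray_physics.mask.any():
        warnings.warn("no rays intersect the metal; beam-hardening correction is a no-op")
        return pm.copy()
    out = pm.copy()
    m = ray_physics.mask
    out[m] = pm[m] * ray_physics.mu_m[m] / ray_physics.mu_m_ave
    return out
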