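"""Metal-induced quantum and electronic noise.

Inserting a strongly attenuating object into measured projections
reduces the transmitted photon count from N = N0 exp(-Por) to
N' = N exp(-Pm), which raises the variance of the log-domain projection
value.  Modelling the detected counts as Poisson plus an electronic
noise floor of Ne noise-equivalent quanta, Var(P) ~ (N + Ne) / N^2, so
the variance that must be ADDED to the already-noisy measurement is

    sigma^2 = (N' + Ne)/N'^2 - (N + Ne)/N^2
            = [ Ne (e^{2 Pm} - 1) + N e^{Pm} - N ] / N^2,   N = N0 e^{-Por}

The inserted noise element is Pn = sigma * x with x standard normal,
applied only to rays that intersect the metal (sigma vanishes when
Pm = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseParams",
    "metal_noise_std",
    "sample_metal_noise",
    "sample_acquisition_noise",
]


@dataclass(frozen=True)
class NoiseParams:
    """Incident flux and electronic noise floor for one acquisition.

    ``n0`` is the incident photon count per detector element per view;
    it may be a scalar, a per-view vector, or a per-(view, channel)
    array (mA-modulation- and bowtie-like flux profiles).  ``ne`` is the
    noise-equivalent quanta of the electronic noise floor.
    """

    n0: float | np.ndarray
    ne: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if np.any(np.asarray(self.n0) <= 0):
            raise ValueError("incident photon count N0 must be positive")
        if self.ne < 0:
            raise ValueError("electronic noise floor Ne must be nonnegative")


def _broadcast_n0(n0, shape):
    """Broadcast scalar / per-view / per-(view, channel) N0 to a field shape."""
    n0 = np.asarray(n0, dtype=float)
    if n0.ndim == 0:
        return n0
    if n0.ndim == 1 and n0.shape[0] == shape[0]:
        return n0.reshape((-1,) + (1,) * (len(shape) - 1))
    if n0.ndim == 2 and n0.shape == shape[:2]:
        return n0.reshape(n0.shape + (1,) * (len(shape) - 2))
    if n0.shape == shape:
        return n0
    raise ValueError(f"N0 of shape {n0.shape} cannot broadcast to projections {shape}")


def metal_noise_std(p_metal, p_original, n0, ne=0.0):
    """Standard deviation of the inserted noise element (dimensionless).

    sigma = sqrt(Ne (e^{2 Pm} - 1) + N0 e^{-Por} (e^{Pm} - 1)) / (N0 e^{-Por})

    Vanishes where ``p_metal`` is zero: no metal, no added noise.
    """
    pm = np.asarray(p_metal, dtype=float)
    por = np.asarray(p_original, dtype=float)
    if np.any(np.asarray(n0) <= 0):
        raise ValueError("incident photon count N0 must be positive")
    if ne < 0:
        raise ValueError("electronic noise floor Ne must be nonnegative")
    if np.any(pm < 0) or np.any(por < 0):
        raise ValueError("line integrals must be nonnegative")
    n = _broadcast_n0(n0, pm.shape if pm.shape else (1,)) * np.exp(-por)
    var = (ne * np.expm1(2.0 * pm) + n * np.expm1(pm)) / n**2
    out = np.sqrt(var)
    return float(out) if np.isscalar(p_metal) and np.isscalar(p_original) else out


def sample_metal_noise(p_metal, p_original, params: NoiseParams, rng=None):
    """Sample the noise field Pn = sigma * x over a projection field.

    ``x`` is i.i.d. standard normal per ray; the field is exactly zero
    off the metal-ray support.  Reproducible for a fixed seed.
    """
    pm = np.asarray(p_metal, dtype=float)
    por = np.asarray(p_original, dtype=float)
    if pm.shape != por.shape:
        raise ValueError(
            f"metal and original projections differ in shape: {pm.shape} vs {por.shape}"
        )
    if rng is None:
        rng = np.random.default_rng(params.seed)
    sigma = metal_noise_std(pm, por, params.n0, params.ne)
    pn = sigma * rng.standard_normal(pm.shape)
    pn[pm <= 0] = 0.0
    return pn

def sample_acquisition_noise(p, n0, ne=0.0, rng=None):
    """Measurement noise for a clean simulated sinogram.

    Gaussian approximation of compound Poisson + electronic noise in the
    log domain, Var(P) = (N + Ne)/N^2 with N = N0 exp(-P).  Used to give
    simulated baseline acquisitions a realistic noise level before
    insertion; the real framework starts from measured (already noisy)
    projections.
    """
    p = np.asarray(p, dtype=float)
    if rng is None:
        rng = np.random.default_rng()
    n = _broadcast_n0(n0, p.shape) * np.exp(-p)
    sigma = np.sqrt((n + ne) / n**2)
    return p + sigma * rng.standard_normal(p.shape)
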